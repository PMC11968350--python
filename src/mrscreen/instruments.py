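"""Instrument selection and quality control.

Candidate instruments pass, in order: a per-trait-class p-value threshold,
greedy LD clumping against a squared-correlation matrix, exclusion of variants
already associated with the outcome, a weak-instrument F filter, and
per-variant Steiger filtering (variance explained on the outcome must not
exceed that on the exposure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import AssociationRecord, HarmonizedPair, SummaryStatsTable

logger = logging.getLogger(__name__)

#: trait classes analysed at a looser threshold because their source GWAS
#: yield few genome-wide-significant loci
AUTO_P_THRESHOLDS = {
    "gut_microbiota": 1e-5,
    "metabolite": 1e-5,
    "skin_microbiota": 5e-5,
}
GENOME_WIDE_P = 5e-8

WEAK_F_CUTOFF = 10.0
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_OUTCOME_P = 0.05


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over a set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise ValueError(f"r2 must be {m}x{m}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if (self.r2 < 0).any() or (self.r2 > 1).any():
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def submatrix(self, ids: list[str]) -> np.ndarray:
        try:
            idx = [self._index[v] for v in ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} missing from LD matrix") from exc
        return self.r2[np.ix_(idx, idx)]


def read_ld_matrix(path) -> LDMatrix:
    """Read a square TSV with a header row of variant ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(variant_ids=[str(c) for c in df.columns], r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")


def select_by_pvalue(table: SummaryStatsTable, threshold: float | str = "auto") -> SummaryStatsTable:
    """Keep rows with ``pval < threshold``.

    ``"auto"`` resolves the threshold from the table's trait class:
    1e-5 for gut microbiota and metabolites, 5e-5 for skin microbiota,
    genome-wide 5e-8 for everything else.
    """
    if threshold == "auto":
        threshold = AUTO_P_THRESHOLDS.get(table.trait_class, GENOME_WIDE_P)
    return table.subset(table.df["pval"].to_numpy() < float(threshold))


def resolve_threshold(trait_class: str) -> float:
    return AUTO_P_THRESHOLDS.get(trait_class, GENOME_WIDE_P)


def clump(candidates: SummaryStatsTable, ld: LDMatrix, r2_threshold: float = DEFAULT_CLUMP_R2) -> SummaryStatsTable:
    """Greedy LD clumping.

    Candidates are visited by ascending p (ties broken lexicographically on
    variant id); a variant is kept iff its r² with every previously kept
    variant is below ``r2_threshold``.
    """
    df = candidates.df
    ids = [str(s) for s in df["SNP"]]
    r2 = ld.submatrix(ids)  # raises on missing candidates
    order = sorted(range(len(ids)), key=lambda i: (df["pval"].iat[i], ids[i]))
    kept: list[int] = []
    for i in order:
        if all(r2[i, k] < r2_threshold for k in kept):
            kept.append(i)
    mask = np.zeros(len(ids), dtype=bool)
    mask[kept] = True
    return candidates.subset(mask)


def _r2_from_pn(pval, n):
    """r² implied by a p-value at sample size n: t²/(t² + n − 2)."""
    pval = np.asarray(pval, dtype=float)
    n = np.asarray(n, dtype=float)
    if (n <= 2).any():
        raise ValueError("sample size must exceed 2")
    # guard against underflowed p, where isf would return inf
    t = stats.t.isf(np.minimum(np.maximum(pval, 1e-300), 1.0) / 2.0, df=n - 2)
    return t * t / (t * t + n - 2)


def r_squared_per_variant(record: AssociationRecord, mode: str = "from_pn") -> float:
    """Fraction of trait variance explained by one variant.

    ``from_pn`` inverts the two-sided t test at df n−2; ``from_beta_eaf``
    uses 2·eaf·(1−eaf)·beta² (standardized trait).
    """
    if mode == "from_pn":
        if record.n is None:
            raise ValueError(f"{record.variant_id}: from_pn mode requires n")
        if record.beta == 0:
            return 0.0
        return float(_r2_from_pn(record.pval, record.n))
    if mode == "from_beta_eaf":
        if record.eaf is None:
            raise ValueError(f"{record.variant_id}: from_beta_eaf mode requires eaf")
        return float(2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2)
    raise ValueError(f"unknown mode {mode!r}")


def f_statistic(R2: float, n: float, k: int) -> float:
    """Instrument-strength F statistic: F = [R²·(n−k−1)] / [k·(1−R²)]."""
    if not 0 <= R2 < 1:
        raise ValueError(f"R2 must lie in [0, 1), got {R2}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"n must exceed k+1, got n={n}, k={k}")
    return (R2 * (n - k - 1)) / (k * (1 - R2))


def exclude_outcome_associated(pair: HarmonizedPair, p_cut: float = DEFAULT_OUTCOME_P) -> HarmonizedPair:
    """Drop instruments already associated with the outcome at p < ``p_cut``.

    The p-value is recomputed as 2·Φ(−|Γ/σ_y|) so the rule also applies to
    synthetic pairs lacking a stored outcome p column.
    """
    z = np.abs(pair.Gamma / pair.se_Gamma)
    p = 2.0 * stats.norm.sf(z)
    return pair.subset(p >= p_cut, drop_reason="outcome_associated", drop_stats=p)


def outcome_p_values(pair: HarmonizedPair) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(pair.Gamma / pair.se_Gamma))


def exposure_p_values(pair: HarmonizedPair) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(pair.gamma / pair.se_gamma))


def per_variant_f(pair: HarmonizedPair) -> np.ndarray:
    """Single-variant (k=1) F statistics from p and n on the exposure side."""
    r2 = _r2_from_pn(exposure_p_values(pair), pair.exposure_n)
    n = pair.exposure_n
    return (r2 * (n - 2)) / (1 - r2)


def filter_weak(pair: HarmonizedPair, f_cutoff: float = WEAK_F_CUTOFF) -> HarmonizedPair:
    """Remove variants whose single-instrument F falls below ``f_cutoff``."""
    f = per_variant_f(pair)
    return pair.subset(f >= f_cutoff, drop_reason="weak_instrument", drop_stats=f)


def steiger_filter(pair: HarmonizedPair) -> HarmonizedPair:
    """Per-variant Steiger filter.

    Drops variants whose variance explained on the outcome exceeds that on the
    exposure (``steiger_reverse``); exact ties are kept and flagged.
    """
    r2_exp = _r2_from_pn(exposure_p_values(pair), pair.exposure_n)
    r2_out = _r2_from_pn(outcome_p_values(pair), pair.outcome_n)
    keep = r2_out <= r2_exp
    out = pair.subset(keep, drop_reason="steiger_reverse", drop_stats=r2_out - r2_exp)
    ties = [vid for vid, k, tie in zip(pair.variant_ids, keep, r2_out == r2_exp) if k and tie]
    if ties:
        out.flags.setdefault("steiger_tie", []).extend(ties)
    return out


@dataclass
class InstrumentSet:
    """Surviving instruments with aggregate strength statistics."""

    pair: HarmonizedPair
    k: int
    R2_total: float
    F_aggregate: float
    filter_log: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_instrument_set(pair: HarmonizedPair) -> InstrumentSet:
    """Aggregate R² (sum of per-variant r²) and the set-level F statistic."""
    k = pair.j
    if k == 0:
        return InstrumentSet(pair=pair, k=0, R2_total=0.0, F_aggregate=0.0, filter_log=filter_log_frame(pair))
    r2 = float(_r2_from_pn(exposure_p_values(pair), pair.exposure_n).sum())
    n = float(np.nanmean(pair.exposure_n))
    F = f_statistic(min(r2, 1 - 1e-12), n, k) if n > k + 1 else 0.0
    return InstrumentSet(pair=pair, k=k, R2_total=r2, F_aggregate=F, filter_log=filter_log_frame(pair))


def filter_log_frame(pair: HarmonizedPair) -> pd.DataFrame:
    """Tidy per-variant exclusion log (variant, filter, statistic, decision)."""
    rows = [
        {"variant": e.variant_id, "filter": e.reason, "statistic": e.statistic, "decision": "drop"}
        for e in pair.drop_log
    ]
    rows += [
        {"variant": v, "filter": "all", "statistic": None, "decision": "keep"}
        for v in pair.variant_ids
    ]
    return pd.DataFrame(rows, columns=["variant", "filter", "statistic", "decision"])
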