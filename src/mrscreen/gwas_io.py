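"""GWAS summary-statistics data model, tabular IO, and allele harmonization.

The central containers are :class:`SummaryStatsTable` (one trait's per-variant
association statistics, DataFrame-backed) and :class:`HarmonizedPair` (the
allele-aligned exposure/outcome effect vectors that every MR estimator
consumes). Harmonization resolves strand and allele-order differences between
two GWAS and drops palindromic variants whose orientation cannot be inferred
from allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for the bundled summary-stat dialect
CANONICAL_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

#: bundled dialect matching common GWAS summary-stat exports
CANONICAL_DIALECT: Mapping[str, str] = {c: c for c in CANONICAL_COLUMNS}

TRAIT_CLASSES = frozenset(
    {
        "gut_microbiota",
        "skin_microbiota",
        "metabolite",
        "wbc",
        "immune_cell",
        "inflammatory_protein",
        "inflammatory_cytokine",
        "disease",
    }
)


class ValidationError(ValueError):
    """A summary-statistics table violated its contract."""


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's summary association for one trait.

    ``beta`` is the per-effect-allele effect on the trait (log-odds for binary
    traits); ``se`` its standard error; ``eaf`` the effect-allele frequency.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validation_errors(self) -> list[str]:
        msgs = []
        if self.effect_allele not in VALID_ALLELES:
            msgs.append(f"effect_allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            msgs.append(f"other_allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            msgs.append(f"effect_allele equals other_allele ({self.effect_allele!r})")
        if not self.se > 0:
            msgs.append(f"se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            msgs.append(f"pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not np.isnan(self.eaf) and not (0 < self.eaf < 1):
            msgs.append(f"eaf must be in (0, 1), got {self.eaf}")
        if self.n is not None and self.n <= 0:
            msgs.append(f"n must be positive, got {self.n}")
        return msgs

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


def _check_pval_consistency(df: pd.DataFrame, trait_id: str, rtol: float = 0.10) -> None:
    """Warn when the reported p disagrees with |beta/se| under the normal
    approximation by more than ``rtol`` on the z scale."""
    z_obs = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
    p = df["pval"].to_numpy(dtype=float)
    # implied |z| from the two-sided p; skip underflowed p where isf saturates
    ok = (p > 1e-280) & (p < 1.0)
    if not ok.any():
        return
    z_imp = stats.norm.isf(p[ok] / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(z_obs[ok] - z_imp) / np.maximum(z_imp, 1e-12)
    bad = (rel > rtol) & (z_imp > 0.1)
    if bad.any():
        ids = df.loc[df.index[ok][bad], "SNP"].tolist()[:5]
        logger.warning(
            "%s: reported p inconsistent with beta/se (>%.0f%% on z scale) for %d "
            "variant(s), e.g. %s", trait_id, rtol * 100, int(bad.sum()), ids,
        )


@dataclass
class SummaryStatsTable:
    """Ordered per-variant association statistics for one trait."""

    trait_id: str
    trait_class: str
    df: pd.DataFrame
    n_default: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in ("SNP", "effect_allele", "other_allele", "beta", "se", "pval") if c not in df.columns]
        if missing:
            raise ValidationError(f"{self.trait_id}: missing required column(s): {', '.join(missing)}")
        if self.trait_class not in TRAIT_CLASSES:
            raise ValidationError(
                f"{self.trait_id}: unknown trait_class {self.trait_class!r}; "
                f"expected one of {sorted(TRAIT_CLASSES)}"
            )
        for col in ("eaf", "n"):
            if col not in df.columns:
                df[col] = np.nan
        errors: list[str] = []
        dup = df["SNP"][df["SNP"].duplicated()].unique().tolist()
        if dup:
            errors.append(f"duplicate variant_id(s): {', '.join(map(str, dup))}")
        for row_no, rec in enumerate(self.records(), start=1):
            for msg in rec.validation_errors():
                errors.append(f"row {row_no} ({rec.variant_id}): {msg}")
        if errors:
            raise ValidationError(f"{self.trait_id}: " + "; ".join(errors))
        _check_pval_consistency(df, self.trait_id)

    def records(self) -> Iterator[AssociationRecord]:
        for row in self.df.itertuples(index=False):
            n = getattr(row, "n", np.nan)
            eaf = getattr(row, "eaf", np.nan)
            yield AssociationRecord(
                variant_id=str(row.SNP),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                eaf=None if pd.isna(eaf) else float(eaf),
                n=None if pd.isna(n) else int(n),
            )

    def __len__(self) -> int:
        return len(self.df)

    def sample_sizes(self) -> np.ndarray:
        """Per-variant n, filled with ``n_default`` where missing."""
        n = self.df["n"].to_numpy(dtype=float)
        if np.isnan(n).any():
            if self.n_default is None:
                raise ValidationError(
                    f"{self.trait_id}: sample size missing for some variants and no n_default set"
                )
            n = np.where(np.isnan(n), float(self.n_default), n)
        return n

    def subset(self, mask: Sequence[bool]) -> "SummaryStatsTable":
        sub = self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return replace(self, df=sub)


def read_summary_stats(
    path,
    dialect: Mapping[str, str] = CANONICAL_DIALECT,
    trait_id: str | None = None,
    trait_class: str = "disease",
    n_default: int | None = None,
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``dialect`` maps canonical column names (``SNP``, ``effect_allele``, ...)
    to the column names present in the file; ``eaf`` and ``n`` entries are
    optional.
    """
    raw = pd.read_csv(path, sep=sep)
    rename = {}
    for canonical, actual in dialect.items():
        if canonical in ("eaf", "n") and actual not in raw.columns:
            continue
        if actual not in raw.columns:
            raise ValidationError(f"{path}: missing required column {actual!r} (for {canonical})")
        rename[actual] = canonical
    df = raw.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]
    return SummaryStatsTable(
        trait_id=trait_id or str(path),
        trait_class=trait_class,
        df=df.reset_index(drop=True),
        n_default=n_default,
    )


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write the canonical TSV dialect; round-trips bit-identically."""
    out = table.df.reindex(columns=CANONICAL_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DropEntry:
    variant_id: str
    reason: str
    statistic: float | None = None


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure (gamma) and outcome (Gamma) effect vectors.

    Both betas refer to the same effect allele at every variant. ``drop_log``
    records every input variant excluded along the way, with a reason.
    """

    variant_ids: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    eaf: np.ndarray
    exposure_n: np.ndarray
    outcome_n: np.ndarray
    drop_log: list[DropEntry] = field(default_factory=list)
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma", "eaf", "exposure_n", "outcome_n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(self.variant_ids),):
                raise ValueError(f"{name} has length {arr.shape}, expected {len(self.variant_ids)}")
        if (self.se_gamma <= 0).any() or (self.se_Gamma <= 0).any():
            raise ValueError("all standard errors must be > 0")

    @property
    def j(self) -> int:
        return len(self.variant_ids)

    def __len__(self) -> int:
        return self.j

    def subset(self, keep: np.ndarray, drop_reason: str | None = None,
               drop_stats: np.ndarray | None = None) -> "HarmonizedPair":
        """Restrict to ``keep`` (boolean mask); dropped variants are appended
        to the drop log with ``drop_reason``."""
        keep = np.asarray(keep, dtype=bool)
        log = list(self.drop_log)
        if drop_reason is not None:
            for i in np.flatnonzero(~keep):
                stat = float(drop_stats[i]) if drop_stats is not None else None
                log.append(DropEntry(self.variant_ids[i], drop_reason, stat))
        return HarmonizedPair(
            variant_ids=[v for v, k in zip(self.variant_ids, keep) if k],
            gamma=self.gamma[keep],
            se_gamma=self.se_gamma[keep],
            Gamma=self.Gamma[keep],
            se_Gamma=self.se_Gamma[keep],
            eaf=self.eaf[keep],
            exposure_n=self.exposure_n[keep],
            outcome_n=self.outcome_n[keep],
            drop_log=log,
            flags={k: list(v) for k, v in self.flags.items()},
        )

    def without(self, index: int) -> "HarmonizedPair":
        keep = np.ones(self.j, dtype=bool)
        keep[index] = False
        return self.subset(keep)


def _match_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """Classify the outcome alleles relative to the exposure's.

    Returns "same", "swap", "flip" (strand complement), "flip_swap", or None.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "flip"
    if (cea, coa) == (oa_x, ea_x):
        return "flip_swap"
    return None


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect alleles.

    Rules, per shared variant: identical alleles are kept as-is; swapped
    alleles negate the outcome beta (and reflect its eaf); otherwise the
    outcome alleles are strand-complemented and the two rules retried.
    Palindromic (A/T, G/C) variants are kept only when both allele frequencies
    fall on the same side of 0.5 and outside the ambiguity window
    ``0.5 ± palindrome_eaf_window``; a missing frequency drops them.
    """
    w = palindrome_eaf_window
    out_idx = {str(s): i for i, s in enumerate(outcome.df["SNP"])}
    exp_ids = [str(s) for s in exposure.df["SNP"]]

    exp_n = exposure.sample_sizes() if exposure.n_default is not None or exposure.df["n"].notna().all() else None
    out_n = outcome.sample_sizes() if outcome.n_default is not None or outcome.df["n"].notna().all() else None

    edf, odf = exposure.df, outcome.df
    keep_ids: list[str] = []
    rows: list[tuple] = []
    drop_log: list[DropEntry] = []

    for i, vid in enumerate(exp_ids):
        jo = out_idx.get(vid)
        if jo is None:
            drop_log.append(DropEntry(vid, "not_in_outcome"))
            continue
        ea_x, oa_x = str(edf.at[i, "effect_allele"]), str(edf.at[i, "other_allele"])
        ea_y, oa_y = str(odf.at[jo, "effect_allele"]), str(odf.at[jo, "other_allele"])
        match = _match_alleles(ea_x, oa_x, ea_y, oa_y)
        if match is None:
            drop_log.append(DropEntry(vid, "allele_mismatch"))
            continue
        palindromic = COMPLEMENT[ea_x] == oa_x
        g = float(edf.at[i, "beta"])
        sg = float(edf.at[i, "se"])
        G = float(odf.at[jo, "beta"])
        sG = float(odf.at[jo, "se"])
        eaf_x = float(edf.at[i, "eaf"]) if pd.notna(edf.at[i, "eaf"]) else np.nan
        eaf_y = float(odf.at[jo, "eaf"]) if pd.notna(odf.at[jo, "eaf"]) else np.nan
        if palindromic:
            # strand is unresolvable from alleles; rely on frequency agreement
            if np.isnan(eaf_x) or np.isnan(eaf_y):
                drop_log.append(DropEntry(vid, "palindromic_ambiguous"))
                continue
            near = abs(eaf_x - 0.5) <= w or abs(eaf_y - 0.5) <= w
            same_side = (eaf_x - 0.5) * (eaf_y - 0.5) > 0
            if near or not same_side:
                drop_log.append(DropEntry(vid, "palindromic_ambiguous"))
                continue
            eaf_use = eaf_x
        else:
            if match in ("swap", "flip_swap"):
                G = -G
                eaf_y = 1.0 - eaf_y if not np.isnan(eaf_y) else eaf_y
            eaf_use = eaf_x if not np.isnan(eaf_x) else eaf_y
        nx = float(exp_n[i]) if exp_n is not None else np.nan
        ny = float(out_n[jo]) if out_n is not None else np.nan
        keep_ids.append(vid)
        rows.append((g, sg, G, sG, eaf_use, nx, ny))

    exp_set = set(exp_ids)
    for vid in (str(s) for s in odf["SNP"]):
        if vid not in exp_set:
            drop_log.append(DropEntry(vid, "not_in_exposure"))

    arr = np.array(rows, dtype=float).reshape(len(rows), 7)
    return HarmonizedPair(
        variant_ids=keep_ids,
        gamma=arr[:, 0],
        se_gamma=arr[:, 1],
        Gamma=arr[:, 2],
        se_Gamma=arr[:, 3],
        eaf=arr[:, 4],
        exposure_n=arr[:, 5],
        outcome_n=arr[:, 6],
        drop_log=drop_log,
    )
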