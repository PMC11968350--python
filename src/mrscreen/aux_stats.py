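"""Cross-cutting statistics: BH-FDR tiering, LDSC-lite, pathway enrichment.

The FDR tiering follows the screening convention FDR < 0.1 → significant,
P_IVW < 0.05 with FDR ≥ 0.1 → suggestive, else null. LDSC-lite is a
deliberately simplified single-step weighted regression of χ² statistics
(and z-score products) on LD scores — adequate for synthetic parameter
recovery, not a reimplementation of the full published LDSC (no jackknife
SEs, no two-step intercept constraint). Pathway enrichment is the classic
hypergeometric over-representation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANT_FDR = 0.1
SUGGESTIVE_P = 0.05
ENRICHMENT_ALPHA = 0.01


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tier(pval: float, fdr: float) -> str:
    """Tier a result: significant (FDR<0.1), suggestive (p<0.05, FDR≥0.1), null."""
    if not (0 <= pval <= 1 and 0 <= fdr <= 1):
        raise ValueError("pval and fdr must lie in [0, 1]")
    if fdr < SIGNIFICANT_FDR:
        return "significant"
    if pval < SUGGESTIVE_P:
        return "suggestive"
    return "null"


@dataclass
class TieredResult:
    pval: float
    fdr: float
    tier: str


def tier_table(pvals, families=None) -> pd.DataFrame:
    """BH-adjust and tier a vector of IVW p-values.

    ``families`` optionally groups the adjustment (e.g. by exposure trait
    class) so each family forms its own multiple-testing correction.
    """
    p = np.asarray(pvals, dtype=float)
    fdr = np.empty_like(p)
    if families is None:
        fdr[:] = bh_fdr(p)
    else:
        fam = np.asarray(families)
        for f in np.unique(fam):
            m = fam == f
            fdr[m] = bh_fdr(p[m])
    tiers = [tier(pi, fi) for pi, fi in zip(p, fdr)]
    return pd.DataFrame({"pval": p, "fdr": fdr, "tier": tiers})


@dataclass
class LdscResult:
    h2_1: float
    h2_2: float
    rho_g: float
    rg: float | None
    rg_clamped: float | None
    intercept_1: float
    intercept_2: float
    intercept_biv: float
    M: int
    flags: list


def ldsc_bivariate(z1, z2, ld_scores, N1: float, N2: float, M: int) -> LdscResult:
    """Bivariate LD-score regression (simplified).

    Univariate: χ²_j regressed on ℓ_j with a free intercept; slope·M/N is the
    SNP heritability. Bivariate: z1_j·z2_j on ℓ_j; slope·M/√(N1·N2) is the
    genetic covariance ρ_g; r_g = ρ_g/√(h²₁·h²₂). Weights 1/max(ℓ_j, 1).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    if not (len(z1) == len(z2) == len(ell)):
        raise ValueError("z1, z2 and ld_scores must have equal length")
    if len(z1) < 50:
        raise ValueError("LDSC regression requires at least 50 variants")
    if (ell < 1).any():
        raise ValueError("LD scores must be >= 1")
    w = 1.0 / np.maximum(ell, 1.0)
    X = sm.add_constant(ell)

    def _wls(y):
        fit = sm.WLS(y, X, weights=w).fit()
        return float(fit.params[1]), float(fit.params[0])

    s1, i1 = _wls(z1 * z1)
    s2, i2 = _wls(z2 * z2)
    sc, ic = _wls(z1 * z2)
    h2_1 = s1 * M / N1
    h2_2 = s2 * M / N2
    rho_g = sc * M / np.sqrt(N1 * N2)
    flags = []
    if h2_1 <= 0 or h2_2 <= 0:
        flags.append("nonpositive_heritability")
        rg = rg_clamped = None
    else:
        rg = float(rho_g / np.sqrt(h2_1 * h2_2))
        rg_clamped = float(np.clip(rg, -1.0, 1.0))
        if rg != rg_clamped:
            flags.append("rg_clamped")
    return LdscResult(
        h2_1=float(h2_1), h2_2=float(h2_2), rho_g=float(rho_g),
        rg=rg, rg_clamped=rg_clamped,
        intercept_1=i1, intercept_2=i2, intercept_biv=ic,
        M=int(M), flags=flags,
    )


@dataclass
class PathwayLibrary:
    """Mapping of pathway name to the set of member compound ids."""

    pathways: dict[str, frozenset]

    @classmethod
    def from_tsv(cls, path) -> "PathwayLibrary":
        df = pd.read_csv(path, sep="\t")
        groups = df.groupby("pathway_name")["compound_id"].apply(frozenset)
        return cls(pathways={str(k): v for k, v in groups.items()})

    def to_tsv(self, path) -> None:
        rows = [(name, cid) for name, members in sorted(self.pathways.items())
                for cid in sorted(members)]
        pd.DataFrame(rows, columns=["pathway_name", "compound_id"]).to_csv(path, sep="\t", index=False)


def hypergeom_enrich(hits, library: PathwayLibrary, universe) -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway.

    Upper-tail p = P(X ≥ k) for X ~ Hypergeom(M, K, n) with M the universe
    size, K the pathway size within the universe, n the hit-list size and k
    the observed overlap. BH-FDR across pathways; ``significant`` marks raw
    p < 0.01.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = frozenset(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M, n = len(universe), len(hits)
    rows = []
    for name, members in sorted(library.pathways.items()):
        in_universe = members & universe
        K = len(in_universe)
        k = len(in_universe & hits)
        pval = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({"pathway": name, "K": K, "n": n, "k": k, "pval": min(pval, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["pval"].to_numpy())
    out["significant"] = out["pval"] < ENRICHMENT_ALPHA
    return out.sort_values("pval", kind="mergesort").reset_index(drop=True)
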