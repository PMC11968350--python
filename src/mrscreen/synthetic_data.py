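"""Synthetic GWAS summary statistics with known ground truth.

Summary statistics are generated directly at the summary level: each
variant's observed per-allele effect is drawn from a normal around its true
effect with sampling SE σ = 1/√(2·maf·(1−maf)·n) (standardized trait). This
is orders of magnitude faster than simulating individual-level genotypes and
reproduces exactly the sampling model the MR estimators assume. Winner's
curse and sample-overlap artifacts are absent unless explicitly injected via
``selection_threshold`` / ``overlap_rho``.

The module provides the full triplet generator (exposure → mediator →
outcome tables with block LD and a ground-truth record), fast
:class:`~mrscreen.gwas_io.HarmonizedPair` generators for calibration studies,
an LDSC input generator, and a toy pathway-library generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import HarmonizedPair, SummaryStatsTable
from .instruments import LDMatrix

_P_FLOOR = 1e-320

# non-palindromic allele pairs only, so harmonization never drops variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class PleiotropyConfig:
    """Direct variant→outcome effects bypassing the exposure."""

    fraction: float = 0.0
    mean: float = 0.0
    sd: float = 0.0


@dataclass
class LDConfig:
    """AR(1) correlation within consecutive blocks of variants."""

    block_size: int = 10
    rho: float = 0.5


@dataclass
class ChainConfig:
    """A known causal chain exposure →(a)→ mediator →(b)→ outcome, with a
    direct exposure→outcome effect c_prime. Total effect = c_prime + a·b."""

    a: float = 0.3
    b: float = 0.4
    c_prime: float = 0.1
    j_mediator: int = 30


@dataclass
class SimConfig:
    m_snps: int = 300
    j_causal: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    # defaults emulate the screening regime: small exposure/mediator GWAS
    # (microbiome/metabolite scale) against a binary outcome whose effective
    # sample size on the observed log-odds scale leaves per-instrument outcome
    # associations weak — the regime in which the outcome-overlap exclusion
    # (p < 0.05) retains most instruments
    n_exposure: int = 8_000
    n_mediator: int = 8_000
    n_outcome: int = 5_000
    beta_total: float | None = 0.2
    chain: ChainConfig | None = None
    per_variant_r2: float = 0.003
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    ld: LDConfig = field(default_factory=LDConfig)
    selection_threshold: float | None = None
    overlap_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_causal > self.m_snps:
            raise ValueError("j_causal cannot exceed m_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        if not 0 <= self.pleiotropy.fraction <= 1:
            raise ValueError("pleiotropy fraction must lie in [0, 1]")
        if not 0 <= self.ld.rho < 1:
            raise ValueError("ld rho must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated tables."""

    beta_exposure: np.ndarray
    causal_ids: list[str]
    mediator_instrument_ids: list[str]
    pleiotropic_ids: list[str]
    a: float | None
    b: float | None
    c_prime: float | None
    total: float
    indirect: float | None
    proportion: float | None
    ld_r2: np.ndarray


@dataclass
class SimResult:
    exposure: SummaryStatsTable
    mediator: SummaryStatsTable | None
    outcome: SummaryStatsTable
    ld: LDMatrix
    truth: SimTruth


def _sampling_se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, _P_FLOOR, 1.0)


def _observe(true: np.ndarray, se: np.ndarray, rng: np.random.Generator,
             noise: np.ndarray | None = None) -> np.ndarray:
    if noise is None:
        noise = rng.standard_normal(true.shape)
    return true + se * noise


def _table(trait_id, trait_class, ids, ea, oa, maf, beta, se, n) -> SummaryStatsTable:
    df = pd.DataFrame({
        "SNP": ids, "effect_allele": ea, "other_allele": oa,
        "eaf": maf, "beta": beta, "se": se, "pval": _pvals(beta, se),
        "n": np.full(len(ids), int(n)),
    })
    return SummaryStatsTable(trait_id=trait_id, trait_class=trait_class, df=df, n_default=int(n))


def simulate_triplet(config: SimConfig) -> SimResult:
    """Generate exposure/mediator/outcome summary statistics with block LD.

    True exposure effects sit on the lead variant of each of the first
    ``j_causal`` LD blocks, scaled so each explains ``per_variant_r2`` of the
    exposure variance; non-lead variants in a block carry the lead effect
    attenuated by the AR(1) correlation r = rho^distance. Mediator-specific
    instruments (when a chain is configured) occupy the following blocks.
    Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_snps
    bs = cfg.ld.block_size
    n_blocks = int(np.ceil(m / bs))
    block_of = np.arange(m) // bs
    pos_in_block = np.arange(m) % bs

    need = cfg.j_causal + (cfg.chain.j_mediator if cfg.chain else 0)
    if need > n_blocks:
        raise ValueError(
            f"need {need} blocks for causal+mediator leads but only {n_blocks} available; "
            "increase m_snps or block_size"
        )

    ids = [f"rs{i + 1:06d}" for i in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    # AR(1) correlation within blocks; r2 is block-diagonal
    dist = np.abs(np.subtract.outer(pos_in_block, pos_in_block))
    same_block = np.equal.outer(block_of, block_of)
    r = np.where(same_block, cfg.ld.rho**dist, 0.0)
    np.fill_diagonal(r, 1.0)
    ld = LDMatrix(variant_ids=ids, r2=r * r)

    # true exposure effects: leads of the first j_causal blocks, LD-propagated
    lead_idx = np.arange(n_blocks) * bs
    causal_leads = lead_idx[: cfg.j_causal]
    beta_x = np.zeros(m)
    signs = rng.choice([-1.0, 1.0], size=cfg.j_causal)
    for lead, s in zip(causal_leads, signs):
        mag = np.sqrt(cfg.per_variant_r2 / (2.0 * maf[lead] * (1.0 - maf[lead])))
        blk = block_of == block_of[lead]
        beta_x[blk] = s * mag * r[lead, blk]

    if cfg.chain is not None:
        a, b, c_prime = cfg.chain.a, cfg.chain.b, cfg.chain.c_prime
        total = c_prime + a * b
        med_leads = lead_idx[cfg.j_causal: cfg.j_causal + cfg.chain.j_mediator]
        beta_m_own = np.zeros(m)
        msigns = rng.choice([-1.0, 1.0], size=len(med_leads))
        for lead, s in zip(med_leads, msigns):
            mag = np.sqrt(cfg.per_variant_r2 / (2.0 * maf[lead] * (1.0 - maf[lead])))
            blk = block_of == block_of[lead]
            beta_m_own[blk] = s * mag * r[lead, blk]
        beta_med = a * beta_x + beta_m_own
        beta_out = total * beta_x + b * beta_m_own
        mediator_ids = [ids[i] for i in med_leads]
    else:
        if cfg.beta_total is None:
            raise ValueError("config must set beta_total or chain")
        a = b = c_prime = None
        total = cfg.beta_total
        beta_med = None
        beta_out = total * beta_x
        mediator_ids = []

    # directional or balanced horizontal pleiotropy on causal variants
    pleio_ids: list[str] = []
    if cfg.pleiotropy.fraction > 0:
        n_pleio = int(round(cfg.pleiotropy.fraction * cfg.j_causal))
        chosen = rng.choice(causal_leads, size=n_pleio, replace=False)
        beta_out = beta_out.copy()
        beta_out[chosen] += rng.normal(cfg.pleiotropy.mean, cfg.pleiotropy.sd, size=n_pleio)
        pleio_ids = [ids[i] for i in sorted(chosen)]

    se_x = _sampling_se(maf, cfg.n_exposure)
    se_y = _sampling_se(maf, cfg.n_outcome)
    if cfg.overlap_rho:
        zx = rng.standard_normal(m)
        zy = cfg.overlap_rho * zx + np.sqrt(1 - cfg.overlap_rho**2) * rng.standard_normal(m)
        obs_x = _observe(beta_x, se_x, rng, zx)
        obs_y = _observe(beta_out, se_y, rng, zy)
    else:
        obs_x = _observe(beta_x, se_x, rng)
        obs_y = _observe(beta_out, se_y, rng)

    if cfg.selection_threshold is not None:
        # winner's-curse injection: causal variants are re-drawn until their
        # observed exposure p passes the selection threshold (capped retries)
        zc = stats.norm.isf(cfg.selection_threshold / 2.0)
        for i in causal_leads:
            tries = 0
            while abs(obs_x[i] / se_x[i]) < zc and tries < 1000:
                obs_x[i] = beta_x[i] + se_x[i] * rng.standard_normal()
                tries += 1

    exposure = _table("sim_exposure", "gut_microbiota", ids, ea, oa, maf, obs_x, se_x, cfg.n_exposure)
    outcome = _table("sim_outcome", "disease", ids, ea, oa, maf, obs_y, se_y, cfg.n_outcome)
    mediator = None
    if beta_med is not None:
        se_m = _sampling_se(maf, cfg.n_mediator)
        obs_m = _observe(beta_med, se_m, rng)
        mediator = _table("sim_mediator", "metabolite", ids, ea, oa, maf, obs_m, se_m, cfg.n_mediator)

    truth = SimTruth(
        beta_exposure=beta_x,
        causal_ids=[ids[i] for i in causal_leads],
        mediator_instrument_ids=mediator_ids,
        pleiotropic_ids=pleio_ids,
        a=a, b=b, c_prime=c_prime,
        total=total,
        indirect=(a * b) if a is not None else None,
        proportion=(100.0 * a * b / total) if a is not None else None,
        ld_r2=ld.r2,
    )
    return SimResult(exposure=exposure, mediator=mediator, outcome=outcome, ld=ld, truth=truth)


def _pair_from_arrays(prefix, beta_g, se_g, beta_G, se_G, maf, n1, n2, rng) -> HarmonizedPair:
    j = len(beta_g)
    obs_g = beta_g + se_g * rng.standard_normal(j)
    obs_G = beta_G + se_G * rng.standard_normal(j)
    return HarmonizedPair(
        variant_ids=[f"{prefix}{i + 1:04d}" for i in range(j)],
        gamma=obs_g, se_gamma=se_g, Gamma=obs_G, se_Gamma=se_G,
        eaf=maf,
        exposure_n=np.full(j, float(n1)),
        outcome_n=np.full(j, float(n2)),
    )


def simulate_pair(
    j: int,
    true_beta: float,
    n_exposure: int = 50_000,
    n_outcome: int = 100_000,
    per_variant_r2: float = 0.003,
    maf_range: tuple[float, float] = (0.1, 0.5),
    pleiotropy_fraction: float = 0.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    pleiotropy_relative: bool = False,
    orient_positive: bool = False,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> HarmonizedPair:
    """Fast generator of an already-harmonized instrument set.

    Produces ``j`` independent strong instruments (each explaining
    ``per_variant_r2`` of the exposure variance) with a true causal effect
    ``true_beta`` and optional horizontal pleiotropy on a fraction of them.
    With ``pleiotropy_relative`` the direct-effect mean/sd are expressed as
    multiples of each variant's outcome sampling SE, which keeps the direct
    effects heteroscedasticity-matched to the sampling noise.
    ``orient_positive`` fixes the effect-allele labelling so every true
    exposure effect is positive (the orientation under which directional
    pleiotropy stays directional in ratio space). Workhorse for
    calibration and parameter-recovery studies, where regenerating full
    tables and re-harmonizing every replicate would be wasteful.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=j)
    signs = np.ones(j) if orient_positive else rng.choice([-1.0, 1.0], size=j)
    beta_x = signs * np.sqrt(per_variant_r2 / (2 * maf * (1 - maf)))
    beta_y = true_beta * beta_x
    se_x = _sampling_se(maf, n_exposure)
    se_y = _sampling_se(maf, n_outcome)
    if pleiotropy_fraction > 0:
        n_pleio = int(round(pleiotropy_fraction * j))
        idx = rng.choice(j, size=n_pleio, replace=False)
        scale = se_y[idx] if pleiotropy_relative else 1.0
        beta_y = beta_y.copy()
        beta_y[idx] += scale * rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_pleio)
    return _pair_from_arrays("rs", beta_x, se_x, beta_y, se_y, maf, n_exposure, n_outcome, rng)


def simulate_chain_pairs(
    a: float = 0.3,
    b: float = 0.4,
    c_prime: float = 0.1,
    j_exposure: int = 30,
    j_mediator: int = 30,
    n_exposure: int = 50_000,
    n_mediator: int = 50_000,
    n_outcome: int = 100_000,
    per_variant_r2: float = 0.003,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, HarmonizedPair]:
    """Harmonized pairs for the three MR fits of a mediation chain.

    Returns pairs keyed ``exposure_mediator`` (step A), ``mediator_outcome``
    (step B, using mediator-specific instruments) and ``exposure_outcome``
    (total effect, c = c_prime + a·b).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    total = c_prime + a * b
    maf_e = rng.uniform(0.1, 0.5, size=j_exposure)
    beta_x = rng.choice([-1.0, 1.0], size=j_exposure) * np.sqrt(per_variant_r2 / (2 * maf_e * (1 - maf_e)))
    maf_m = rng.uniform(0.1, 0.5, size=j_mediator)
    beta_m = rng.choice([-1.0, 1.0], size=j_mediator) * np.sqrt(per_variant_r2 / (2 * maf_m * (1 - maf_m)))
    return {
        "exposure_mediator": _pair_from_arrays(
            "re", beta_x, _sampling_se(maf_e, n_exposure), a * beta_x,
            _sampling_se(maf_e, n_mediator), maf_e, n_exposure, n_mediator, rng),
        "mediator_outcome": _pair_from_arrays(
            "rm", beta_m, _sampling_se(maf_m, n_mediator), b * beta_m,
            _sampling_se(maf_m, n_outcome), maf_m, n_mediator, n_outcome, rng),
        "exposure_outcome": _pair_from_arrays(
            "re", beta_x, _sampling_se(maf_e, n_exposure), total * beta_x,
            _sampling_se(maf_e, n_outcome), maf_e, n_exposure, n_outcome, rng),
    }


def simulate_ldsc_inputs(
    h2_1: float,
    h2_2: float,
    rg: float,
    N1: int,
    N2: int,
    M: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (z1, z2, ld_scores) under the bivariate LDSC model.

    Var(z_i) = 1 + N_i·h²_i·ℓ_j/M and Cov(z1, z2) = rg·√(h²₁h²₂)·√(N1N2)·ℓ_j/M,
    with LD scores ℓ_j drawn from a shifted gamma (minimum 1).
    """
    if not (0 <= h2_1 <= 1 and 0 <= h2_2 <= 1):
        raise ValueError("heritabilities must lie in [0, 1]")
    if abs(rg) > 1:
        raise ValueError("|rg| must not exceed 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    ell = 1.0 + rng.gamma(shape=4.0, scale=25.0, size=M)
    v1 = 1.0 + N1 * h2_1 * ell / M
    v2 = 1.0 + N2 * h2_2 * ell / M
    cov = rg * np.sqrt(h2_1 * h2_2) * np.sqrt(N1 * N2) * ell / M
    resid = v2 - cov**2 / v1
    if (resid <= 0).any():
        raise ValueError("requested parameters give a non-positive-definite covariance")
    x = rng.standard_normal(M)
    y = rng.standard_normal(M)
    z1 = np.sqrt(v1) * x
    z2 = (cov / np.sqrt(v1)) * x + np.sqrt(resid) * y
    return z1, z2, ell


def make_pathway_library(
    n_pathways: int = 20,
    size_range: tuple[int, int] = (10, 30),
    universe_size: int = 500,
    planted: tuple[str, float] = ("planted_pathway", 10.0),
    n_hits: int = 30,
    seed: int | None = None,
):
    """Random pathway library over a synthetic compound universe, plus a hit
    set in which one planted pathway's members are over-sampled by the given
    enrichment factor.

    Returns (library, hits, universe).
    """
    from .aux_stats import PathwayLibrary

    rng = np.random.default_rng(seed)
    universe = [f"C{i + 1:05d}" for i in range(universe_size)]
    planted_name, factor = planted
    pathways: dict[str, frozenset] = {}
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_pathways)
    for i, sz in enumerate(sizes):
        name = planted_name if i == 0 else f"pathway_{i:03d}"
        members = rng.choice(universe_size, size=int(sz), replace=False)
        pathways[name] = frozenset(universe[j] for j in members)
    weights = np.array([factor if universe[i] in pathways[planted_name] else 1.0
                        for i in range(universe_size)])
    weights /= weights.sum()
    hit_idx = rng.choice(universe_size, size=n_hits, replace=False, p=weights)
    hits = frozenset(universe[i] for i in hit_idx)
    return PathwayLibrary(pathways=pathways), hits, frozenset(universe)
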