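"""Two-sample MR estimators.

All estimators consume a :class:`~mrscreen.gwas_io.HarmonizedPair` (exposure
effects γ_j with SE σ_xj, outcome effects Γ_j with SE σ_yj) and return an
:class:`MREstimate`. IVW — weighted regression of Γ on γ through the origin —
is the primary method; MR-Egger, the weighted median and the weighted mode
relax the no-pleiotropy assumption in different ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .gwas_io import HarmonizedPair

Z95 = 1.959963984540054  # Φ⁻¹(0.975)


@dataclass
class MREstimate:
    """One method's causal effect estimate on the log-odds/linear scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    extras: dict = field(default_factory=dict)


def _finish(method: str, beta: float, se: float, pval: float, nsnp: int, **extras) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(pval),
        nsnp=int(nsnp),
        extras=extras,
    )


def wald_ratios(pair: HarmonizedPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratio estimates β_j = Γ_j/γ_j with first-order SE σ_yj/|γ_j|."""
    zero = pair.gamma == 0
    if zero.any():
        bad = [v for v, z in zip(pair.variant_ids, zero) if z]
        raise ValueError(f"zero exposure effect for variant(s): {', '.join(bad)}")
    ratios = pair.Gamma / pair.gamma
    ses = pair.se_Gamma / np.abs(pair.gamma)
    return ratios, ses


def ivw(pair: HarmonizedPair, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of Γ on γ through the origin with weights 1/σ_yj².
    Under the multiplicative random-effects model (default) the fixed-effect
    SE is inflated by max(1, σ̂) with σ̂² = Q/(J−1), so under-dispersion never
    shrinks the SE below the fixed-effect one.
    """
    J = pair.j
    if J < 2:
        raise ValueError(f"IVW requires at least 2 instruments, got {J}")
    w = 1.0 / pair.se_Gamma**2
    swg2 = float(np.sum(w * pair.gamma**2))
    beta = float(np.sum(w * pair.gamma * pair.Gamma)) / swg2
    se_fixed = swg2**-0.5
    Q = float(np.sum(w * (pair.Gamma - beta * pair.gamma) ** 2))
    sigma2 = Q / (J - 1)
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(sigma2))
    elif effects_model == "fixed":
        se = se_fixed
    else:
        raise ValueError(f"unknown effects_model {effects_model!r}")
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return _finish("ivw_fe" if effects_model == "fixed" else "ivw_re",
                   beta, se, pval, J, Q=Q, sigma_hat=float(np.sqrt(sigma2)), se_fixed=se_fixed)


def egger(pair: HarmonizedPair) -> MREstimate:
    """MR-Egger regression.

    Variants are oriented so every γ_j > 0, then Γ is regressed on γ with a
    free intercept and weights 1/σ_yj². The slope estimates the causal
    effect; the intercept estimates average directional pleiotropy. SEs carry
    the max(1, σ̂) multiplicative inflation; p-values use t with df J−2.
    """
    J = pair.j
    if J < 3:
        raise ValueError(f"MR-Egger requires at least 3 instruments, got {J}")
    sign = np.where(pair.gamma < 0, -1.0, 1.0)
    g = pair.gamma * sign
    G = pair.Gamma * sign
    w = 1.0 / pair.se_Gamma**2
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=w).fit()
    scale = float(fit.scale)  # σ̂² of the weighted fit
    infl = max(1.0, np.sqrt(scale))
    se_unscaled = fit.bse / max(np.sqrt(scale), np.finfo(float).tiny) if scale > 0 else np.sqrt(
        np.diag(np.linalg.inv(X.T @ (w[:, None] * X)))
    )
    se = np.asarray(se_unscaled) * infl
    b0, b1 = fit.params
    se0, se1 = se
    df = J - 2
    p_slope = 2.0 * stats.t.sf(abs(b1 / se1), df)
    p_int = 2.0 * stats.t.sf(abs(b0 / se0), df)
    est = _finish("egger", b1, se1, p_slope, J,
                  intercept=float(b0), intercept_se=float(se0), intercept_pval=float(p_int),
                  sigma_hat=float(np.sqrt(scale)))
    return est


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median with cumulative midpoints S_j = cum(w)−w/2."""
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    k = int(np.searchsorted(s, 0.5))
    return float(b[k - 1] + (b[k] - b[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for (n_boot, J) arrays, vectorized."""
    order = np.argsort(ratios, axis=1)
    b = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - w / 2.0
    n, J = ratios.shape
    k = np.array([np.searchsorted(s[i], 0.5) for i in range(n)])
    k = np.clip(k, 1, J - 1)
    i = np.arange(n)
    lo, hi = b[i, k - 1], b[i, k]
    slo, shi = s[i, k - 1], s[i, k]
    est = lo + (hi - lo) * (0.5 - slo) / (shi - slo)
    est = np.where(0.5 <= s[:, 0], b[:, 0], est)
    est = np.where(0.5 >= s[:, -1], b[:, -1], est)
    return est


def _bootstrap_se(pair: HarmonizedPair, statistic, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample γ*, Γ* from their normals, recompute."""
    rng = np.random.default_rng(seed)
    J = pair.j
    g = rng.normal(pair.gamma, pair.se_gamma, size=(n_boot, J))
    G = rng.normal(pair.Gamma, pair.se_Gamma, size=(n_boot, J))
    g = np.where(g == 0, np.finfo(float).tiny, g)
    ratios = G / g
    weights = g**2 / pair.se_Gamma**2  # inverse variance of the ratio, first order
    reps = statistic(ratios, weights)
    return float(np.std(reps, ddof=1))


def weighted_median(pair: HarmonizedPair, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator: consistent when ≥50% of the weight comes
    from valid instruments. SE from a parametric bootstrap."""
    if pair.j < 3:
        raise ValueError(f"weighted median requires at least 3 instruments, got {pair.j}")
    ratios, ses = wald_ratios(pair)
    weights = 1.0 / ses**2
    beta = _weighted_median(ratios, weights)
    se = _bootstrap_se(pair, _weighted_median_rows, n_boot, seed)
    pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _finish("weighted_median", beta, se, pval, pair.j, n_boot=n_boot, seed=seed)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0:
        return float(ratios[0])
    d = (ratios[:, None] - ratios[None, :]) / h
    dens = (weights[None, :] * np.exp(-0.5 * d * d)).sum(axis=1)
    return float(ratios[int(np.argmax(dens))])


def weighted_mode(pair: HarmonizedPair, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimator: consistent when the largest group of
    instruments sharing one ratio value is valid (ZEMPA assumption).

    The weighted empirical density of the Wald ratios is smoothed with a
    normal kernel of bandwidth h = φ·0.9·min(sd, IQR/1.349)·J^(−1/5) and the
    estimate is the density argmax over the ratio points.
    """
    if pair.j < 3:
        raise ValueError(f"weighted mode requires at least 3 instruments, got {pair.j}")
    ratios, ses = wald_ratios(pair)
    weights = 1.0 / ses**2
    beta = _weighted_mode_point(ratios, weights, phi)

    def stat(r, w):
        return np.array([_weighted_mode_point(r[i], w[i], phi) for i in range(r.shape[0])])

    se = _bootstrap_se(pair, stat, n_boot, seed)
    pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _finish("weighted_mode", beta, se, pval, pair.j, phi=phi, n_boot=n_boot, seed=seed)


def to_odds_ratio(estimate: MREstimate) -> MREstimate:
    """Populate the OR fields: OR = exp(beta), CI = exp(beta ± 1.96·se)."""
    estimate.or_ = float(np.exp(estimate.beta))
    estimate.or_ci_low = float(np.exp(estimate.beta - Z95 * estimate.se))
    estimate.or_ci_high = float(np.exp(estimate.beta + Z95 * estimate.se))
    return estimate


def wald_single(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument Wald ratio estimate (J = 1)."""
    if pair.j != 1:
        raise ValueError("wald_single requires exactly 1 instrument")
    ratios, ses = wald_ratios(pair)
    beta, se = float(ratios[0]), float(ses[0])
    pval = 2.0 * stats.norm.sf(abs(beta / se))
    return _finish("wald", beta, se, pval, 1)
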