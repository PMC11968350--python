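"""Heterogeneity, pleiotropy, outlier and directionality diagnostics.

Cochran's Q, the Egger intercept test, MR-PRESSO (global / outlier /
distortion), leave-one-out estimates and the whole-set Steiger directionality
test, plus the remediation rule the screening pipeline applies when
pleiotropy is detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, egger, ivw
from .gwas_io import HarmonizedPair
from .instruments import _r2_from_pn, exposure_p_values, outcome_p_values


@dataclass
class QResult:
    Q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: list[str]
    outlier_pvals: pd.DataFrame
    distortion_p: float | None
    beta_raw: float
    beta_corrected: float | None
    nb_sim: int
    seed: int


@dataclass
class SteigerResult:
    direction: bool
    r2_exposure: float
    r2_outcome: float
    pval: float


@dataclass
class SensitivityReport:
    Q_ivw: QResult
    Q_egger: QResult | None
    egger_intercept: dict | None
    presso: PressoResult | None
    loo: pd.DataFrame | None
    steiger: SteigerResult | None
    seeds: dict = field(default_factory=dict)


def cochran_q(pair: HarmonizedPair, about: str = "ivw") -> QResult:
    """Cochran's Q heterogeneity statistic about the IVW or Egger fit.

    Q = Σ w_j (Γ_j − fitted_j)² with w_j = 1/σ_yj²; df = J−1 (IVW) or
    J−2 (Egger); p from the chi-square upper tail.
    """
    J = pair.j
    w = 1.0 / pair.se_Gamma**2
    if about == "ivw":
        if J < 2:
            raise ValueError("Q about IVW requires at least 2 instruments")
        est = ivw(pair, effects_model="fixed")
        fitted = est.beta * pair.gamma
        df = J - 1
    elif about == "egger":
        if J < 3:
            raise ValueError("Q about Egger requires at least 3 instruments")
        est = egger(pair)
        sign = np.where(pair.gamma < 0, -1.0, 1.0)
        fitted = sign * (est.extras["intercept"] + est.beta * pair.gamma * sign)
        df = J - 2
    else:
        raise ValueError(f"unknown about {about!r}")
    Q = float(np.sum(w * (pair.Gamma - fitted) ** 2))
    return QResult(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)))


def leave_one_out(pair: HarmonizedPair) -> pd.DataFrame:
    """IVW estimates omitting each variant in turn (one row per variant)."""
    if pair.j < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    rows = []
    for i, vid in enumerate(pair.variant_ids):
        est = ivw(pair.without(i))
        rows.append({"omitted": vid, "beta": est.beta, "se": est.se, "pval": est.pval})
    return pd.DataFrame(rows)


def _loo_ivw_betas(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out index.

    Supports 1-D (J,) or 2-D (n_sim, J) inputs (w stays 1-D)."""
    s1 = np.sum(w * g * g, axis=-1, keepdims=True)
    s2 = np.sum(w * g * G, axis=-1, keepdims=True)
    return (s2 - w * g * G) / (s1 - w * g * g)


def mr_presso(
    pair: HarmonizedPair,
    nb_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO: simulation-based residual sum of squares outlier test.

    Global test: the observed RSS (each variant's weighted squared residual
    about the IVW fit that leaves it out) is compared with its parametric
    null distribution obtained by redrawing γ*, Γ* from their sampling
    normals. Outlier test: each variant's observed residual against its own
    simulated distribution, Bonferroni-adjusted over J. Distortion test:
    permutation of the outlier labels.

    Random draws are keyed to variants sorted by id, so the result is
    invariant to the input ordering of the pair.
    """
    J = pair.j
    if J < 4:
        raise ValueError(f"MR-PRESSO requires at least 4 instruments, got {J}")
    if nb_sim < 100:
        raise ValueError("nb_sim must be at least 100")

    # canonical variant order decouples the random stream from input order
    order = np.argsort(np.asarray(pair.variant_ids, dtype=object))
    ids = [pair.variant_ids[i] for i in order]
    g = pair.gamma[order]
    sg = pair.se_gamma[order]
    G = pair.Gamma[order]
    sG = pair.se_Gamma[order]
    w = 1.0 / sG**2

    beta_loo = _loo_ivw_betas(g, G, w)
    res_obs = w * (G - beta_loo * g) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(nb_sim, J))
    G_star = rng.normal(beta_loo * g, sG, size=(nb_sim, J))
    beta_loo_star = _loo_ivw_betas(g_star, G_star, w)
    res_star = w * (G_star - beta_loo_star * g_star) ** 2
    rss_star = res_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (nb_sim + 1))

    p_var = (1 + np.sum(res_star >= res_obs[None, :], axis=0)) / (nb_sim + 1)
    p_adj = np.minimum(p_var * J, 1.0)
    out_mask = p_adj < outlier_alpha
    outliers = [ids[i] for i in np.flatnonzero(out_mask)]
    outlier_tbl = pd.DataFrame({"variant": ids, "pval": p_var, "pval_bonferroni": p_adj,
                                "outlier": out_mask})

    beta_raw = ivw_slope = float(np.sum(w * g * G) / np.sum(w * g * g))
    beta_corr = None
    distortion_p = None
    n_out = len(outliers)
    if 0 < n_out < J - 1:
        keep = ~out_mask
        beta_corr = float(np.sum(w[keep] * g[keep] * G[keep]) / np.sum(w[keep] * g[keep] ** 2))
        d_obs = beta_corr - beta_raw
        # random subsets of size n_out, vectorized over replicates
        ranks = np.argsort(rng.random((nb_sim, J)), axis=1)
        masks = ranks >= n_out  # keep J - n_out variants per replicate
        num = (masks * (w * g * G)).sum(axis=1)
        den = (masks * (w * g * g)).sum(axis=1)
        d_perm = num / den - ivw_slope
        distortion_p = float((1 + np.sum(np.abs(d_perm) >= abs(d_obs))) / (nb_sim + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outliers=outliers,
        outlier_pvals=outlier_tbl,
        distortion_p=distortion_p,
        beta_raw=beta_raw,
        beta_corrected=beta_corr,
        nb_sim=nb_sim,
        seed=seed,
    )


def steiger_directionality(pair: HarmonizedPair) -> SteigerResult:
    """Whole-set Steiger test of causal direction.

    Compares the total variance explained by the instrument set on the
    exposure vs the outcome; the p-value tests the difference of the
    Fisher-transformed correlations √R² at the two sample sizes.
    """
    if np.isnan(pair.exposure_n).any() or np.isnan(pair.outcome_n).any():
        raise ValueError("Steiger directionality requires sample sizes for both traits")
    r2_exp = float(_r2_from_pn(exposure_p_values(pair), pair.exposure_n).sum())
    r2_out = float(_r2_from_pn(outcome_p_values(pair), pair.outcome_n).sum())
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    n1 = float(np.nanmean(pair.exposure_n))
    n2 = float(np.nanmean(pair.outcome_n))
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(direction=r2_exp > r2_out, r2_exposure=r2_exp, r2_outcome=r2_out, pval=pval)


def sensitivity_report(
    pair: HarmonizedPair,
    nb_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """Run the full diagnostic battery appropriate to the instrument count."""
    J = pair.j
    q_ivw = cochran_q(pair, "ivw")
    q_egger = cochran_q(pair, "egger") if J >= 3 else None
    egger_int = None
    if J >= 3:
        e = egger(pair)
        egger_int = {
            "intercept": e.extras["intercept"],
            "se": e.extras["intercept_se"],
            "pval": e.extras["intercept_pval"],
        }
    presso = mr_presso(pair, nb_sim=nb_sim, outlier_alpha=outlier_alpha, seed=seed) if J >= 4 else None
    loo = leave_one_out(pair) if J >= 3 else None
    steiger = None
    if not (np.isnan(pair.exposure_n).any() or np.isnan(pair.outcome_n).any()):
        steiger = steiger_directionality(pair)
    return SensitivityReport(
        Q_ivw=q_ivw, Q_egger=q_egger, egger_intercept=egger_int,
        presso=presso, loo=loo, steiger=steiger, seeds={"presso": seed},
    )


def remediate_pleiotropy(
    pair: HarmonizedPair,
    report: SensitivityReport,
    nb_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[HarmonizedPair, SensitivityReport, str]:
    """Apply the screening remediation rule.

    If the Egger intercept or the MR-PRESSO global test signals pleiotropy
    (p < alpha), remove the PRESSO outliers and re-run the diagnostics; if
    pleiotropy persists (or there are no outliers to remove) the pair is
    labelled ``pleiotropy_unresolved``. Returns (pair, report, status) where
    status is ``ok``, ``remediated`` or ``pleiotropy_unresolved``.
    """

    def flagged(rep: SensitivityReport) -> bool:
        egger_bad = rep.egger_intercept is not None and rep.egger_intercept["pval"] < alpha
        presso_bad = rep.presso is not None and rep.presso.global_p < alpha
        return egger_bad or presso_bad

    if not flagged(report):
        return pair, report, "ok"
    if report.presso is None or not report.presso.outliers:
        return pair, report, "pleiotropy_unresolved"
    keep = np.array([v not in set(report.presso.outliers) for v in pair.variant_ids])
    reduced = pair.subset(keep, drop_reason="presso_outlier")
    if reduced.j < 2:
        return pair, report, "pleiotropy_unresolved"
    new_report = sensitivity_report(reduced, nb_sim=nb_sim, outlier_alpha=outlier_alpha, seed=seed)
    if flagged(new_report):
        return reduced, new_report, "pleiotropy_unresolved"
    return reduced, new_report, "remediated"
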