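"""Screen orchestration: many exposures against one outcome.

Per exposure the pipeline applies, in order: p-value thresholding (per trait
class), greedy LD clumping, allele harmonization against the outcome,
exclusion of outcome-associated instruments, the weak-instrument F filter and
per-variant Steiger filtering; then the estimator suite, the sensitivity
battery with the pleiotropy remediation rule, and finally per-class BH-FDR
tiering of the primary (IVW) p-values. Everything is deterministic given the
configuration and a seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aux_stats, estimators, instruments, sensitivity
from .gwas_io import HarmonizedPair, SummaryStatsTable, harmonize
from .instruments import LDMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenSettings:
    p_threshold: float | str = "auto"
    clump_r2: float = instruments.DEFAULT_CLUMP_R2
    outcome_p_cut: float = instruments.DEFAULT_OUTCOME_P
    f_cutoff: float = instruments.WEAK_F_CUTOFF
    palindrome_window: float = 0.08
    nb_sim: int = 1000
    outlier_alpha: float = 0.05
    pleiotropy_alpha: float = 0.05
    steiger: bool = True
    fdr_by_class: bool = True
    extra: dict = field(default_factory=dict)


def _pair_seed(seed: int, trait_id: str) -> int:
    """Stable per-pair seed derived from the run seed and the trait id."""
    return (int(seed) * 1_000_003 + zlib.crc32(trait_id.encode())) % (2**31 - 1)


_EST_FIELDS = ("beta", "se", "ci_low", "ci_high", "pval")


def _estimate_columns(pair: HarmonizedPair, seed: int) -> dict:
    cols: dict = {}
    methods: dict = {}
    if pair.j >= 2:
        methods["ivw"] = estimators.ivw(pair)
    elif pair.j == 1:
        methods["ivw"] = estimators.wald_single(pair)
    if pair.j >= 3:
        methods["egger"] = estimators.egger(pair)
        methods["weighted_median"] = estimators.weighted_median(pair, seed=seed)
        methods["weighted_mode"] = estimators.weighted_mode(pair, seed=seed)
    for name in ("ivw", "egger", "weighted_median", "weighted_mode"):
        est = methods.get(name)
        if est is not None:
            est = estimators.to_odds_ratio(est)
        for f in _EST_FIELDS:
            cols[f"{name}_{f}"] = getattr(est, f) if est else np.nan
        cols[f"{name}_or"] = est.or_ if est else np.nan
    if "ivw" in methods:
        cols["primary_method"] = methods["ivw"].method
    return cols


def screen_one(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    settings: ScreenSettings | None = None,
    seed: int = 0,
) -> dict:
    """Run the full per-pair pipeline; returns one tidy result row."""
    st = settings or ScreenSettings()
    row: dict = {
        "exposure": exposure.trait_id,
        "exposure_class": exposure.trait_class,
        "outcome": outcome.trait_id,
        "outcome_class": outcome.trait_class,
    }
    pseed = _pair_seed(seed, exposure.trait_id + "|" + outcome.trait_id)
    try:
        cand = instruments.select_by_pvalue(exposure, st.p_threshold)
        cand = instruments.clump(cand, ld, st.clump_r2)
        pair = harmonize(cand, outcome, st.palindrome_window)
        pair = instruments.exclude_outcome_associated(pair, st.outcome_p_cut)
        pair = instruments.filter_weak(pair, st.f_cutoff)
        if st.steiger:
            pair = instruments.steiger_filter(pair)
    except Exception as exc:  # degrade, never abort the screen
        logger.warning("%s: skipped (%s)", exposure.trait_id, exc)
        row.update(status="skipped_no_instruments", reason=str(exc), nsnp=0)
        return row
    if pair.j == 0:
        row.update(status="skipped_no_instruments", reason="all_instruments_filtered", nsnp=0)
        return row

    status = "ok"
    report = None
    if pair.j >= 2:
        report = sensitivity.sensitivity_report(
            pair, nb_sim=st.nb_sim, outlier_alpha=st.outlier_alpha, seed=pseed)
        pair, report, rstatus = sensitivity.remediate_pleiotropy(
            pair, report, nb_sim=st.nb_sim, outlier_alpha=st.outlier_alpha,
            seed=pseed, alpha=st.pleiotropy_alpha)
        if rstatus == "pleiotropy_unresolved":
            status = "pleiotropy_unresolved"

    row.update(_estimate_columns(pair, pseed))
    row.update(status=status, nsnp=pair.j, seed=pseed)
    iset = instruments.build_instrument_set(pair)
    row.update(R2_total=iset.R2_total, F_aggregate=iset.F_aggregate)
    if report is not None:
        row.update(
            Q=report.Q_ivw.Q, Q_df=report.Q_ivw.df, Q_pval=report.Q_ivw.pval,
            egger_intercept=(report.egger_intercept or {}).get("intercept", np.nan),
            egger_intercept_pval=(report.egger_intercept or {}).get("pval", np.nan),
            presso_global_pval=report.presso.global_p if report.presso else np.nan,
            presso_n_outliers=len(report.presso.outliers) if report.presso else np.nan,
            steiger_direction=report.steiger.direction if report.steiger else np.nan,
            steiger_pval=report.steiger.pval if report.steiger else np.nan,
        )
    row["drop_log"] = ";".join(f"{e.variant_id}:{e.reason}" for e in pair.drop_log)
    return row


def screen(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    settings: ScreenSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward screen of every exposure against one outcome, with per-class
    BH-FDR tiering of the primary IVW p-values."""
    st = settings or ScreenSettings()
    rows = [screen_one(e, outcome, ld, st, seed) for e in exposures]
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    df["tier"] = pd.Series([None] * len(df), dtype=object)
    ok = df["status"].isin(["ok"]) & df.get("ivw_pval", pd.Series(dtype=float)).notna()
    if ok.any():
        p = df.loc[ok, "ivw_pval"].to_numpy(dtype=float)
        fam = df.loc[ok, "exposure_class"].to_numpy() if st.fdr_by_class else None
        tiered = aux_stats.tier_table(p, families=fam)
        df.loc[ok, "fdr"] = tiered["fdr"].to_numpy()
        df.loc[ok, "tier"] = tiered["tier"].to_numpy()
    return df


def reverse_screen(
    disease: SummaryStatsTable,
    outcomes: list[SummaryStatsTable],
    ld: LDMatrix,
    settings: ScreenSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Reverse MR: the disease becomes the exposure (instrumented at the
    genome-wide threshold), each original exposure becomes an outcome."""
    st = settings or ScreenSettings()
    rows = [screen_one(disease, out, ld, st, seed) for out in outcomes]
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    df["tier"] = pd.Series([None] * len(df), dtype=object)
    ok = df["status"].isin(["ok"]) & df.get("ivw_pval", pd.Series(dtype=float)).notna()
    if ok.any():
        tiered = aux_stats.tier_table(df.loc[ok, "ivw_pval"].to_numpy(dtype=float))
        df.loc[ok, "fdr"] = tiered["fdr"].to_numpy()
        df.loc[ok, "tier"] = tiered["tier"].to_numpy()
    return df


def mediation_scan_from_screen(
    forward: pd.DataFrame,
    exposures: dict[str, SummaryStatsTable],
    mediators: dict[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    settings: ScreenSettings | None = None,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Two-step mediation scan over the significant/suggestive forward hits.

    Step A (exposure→mediator) and step B (mediator→outcome) are estimated
    with the same per-pair pipeline; the forward IVW effect supplies the
    total effect c.
    """
    from .mediation import mediation_scan

    st = settings or ScreenSettings()
    hits = forward[forward["tier"].isin(["significant", "suggestive"])]
    totals = hits.rename(columns={"ivw_beta": "beta", "ivw_se": "se", "ivw_pval": "pval"})[
        ["exposure", "beta", "se", "pval"]
    ]
    a_rows, b_rows = [], []
    for med_id, med_table in mediators.items():
        r = screen_one(med_table, outcome, ld, st, seed)
        if r.get("nsnp", 0) >= 1 and not np.isnan(r.get("ivw_beta", np.nan)):
            b_rows.append({"mediator": med_id, "beta": r["ivw_beta"],
                           "se": r["ivw_se"], "pval": r["ivw_pval"]})
        for exp_id in hits["exposure"]:
            ra = screen_one(exposures[exp_id], med_table, ld, st, seed)
            if ra.get("nsnp", 0) >= 1 and not np.isnan(ra.get("ivw_beta", np.nan)):
                a_rows.append({"exposure": exp_id, "mediator": med_id,
                               "beta": ra["ivw_beta"], "se": ra["ivw_se"],
                               "pval": ra["ivw_pval"]})
    step_a = pd.DataFrame(a_rows, columns=["exposure", "mediator", "beta", "se", "pval"])
    step_b = pd.DataFrame(b_rows, columns=["mediator", "beta", "se", "pval"])
    return mediation_scan(totals, step_a, step_b, alpha=alpha)
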