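"""Two-step MR mediation.

Combines three MR estimates — exposure→mediator (a), mediator→outcome (b)
and exposure→outcome (total effect c) — into the indirect effect a·b, the
direct effect c − a·b and the proportion mediated 100·a·b/c, with
first-order delta-method confidence intervals. The two steps come from
separate GWAS samples, so no covariance term enters either variance formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Z95 = 1.959963984540054


@dataclass(frozen=True)
class Effect:
    """An effect estimate with its standard error."""

    beta: float
    se: float
    pval: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be > 0, got {self.se}")


@dataclass
class MediationResult:
    a: Effect
    b: Effect
    c: Effect
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    direct: float
    proportion: float | None
    proportion_se_ratio: float | None
    proportion_se_numerator: float | None
    proportion_ci: tuple[float, float] | None
    consistent: bool
    flags: list[str] = field(default_factory=list)


def two_step_mediation(a: Effect, b: Effect, c: Effect) -> MediationResult:
    """Product-of-coefficients mediation with delta-method CIs.

    indirect = a·b with SE(indirect) = √(a²·SE_b² + b²·SE_a²);
    direct = c − a·b; proportion = 100·a·b/c with the ratio delta SE
    |proportion|·√(SE_ab²/(a·b)² + SE_c²/c²) (the numerator-only SE
    100·SE_ab/|c| is reported alongside). CIs are estimate ± 1.96·SE.
    """
    ab = a.beta * b.beta
    se_ab = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
    direct = c.beta - ab
    flags: list[str] = []

    if c.beta == 0:
        proportion = prop_se_ratio = prop_se_num = prop_ci = None
        flags.append("undefined_proportion_zero_total")
        consistent = False
    else:
        # numpy scalars: extreme inputs yield inf rather than raising
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            proportion = float(100.0 * np.float64(ab) / np.float64(c.beta))
            prop_se_num = float(100.0 * np.float64(se_ab) / abs(np.float64(c.beta)))
            if ab != 0:
                prop_se_ratio = float(abs(proportion) * np.hypot(
                    np.float64(se_ab) / np.float64(ab),
                    np.float64(c.se) / np.float64(c.beta)))
            else:
                prop_se_ratio = prop_se_num
        prop_ci = (proportion - Z95 * prop_se_ratio, proportion + Z95 * prop_se_ratio)
        consistent = np.sign(ab) == np.sign(c.beta)
        if not consistent and ab != 0:
            flags.append("inconsistent_mediation")
        if abs(c.beta) < 2 * c.se:
            flags.append("unstable_total_effect")
        if not 0 <= proportion <= 100:
            flags.append("proportion_outside_0_100")

    return MediationResult(
        a=a, b=b, c=c,
        indirect=ab,
        indirect_se=se_ab,
        indirect_ci=(ab - Z95 * se_ab, ab + Z95 * se_ab),
        direct=direct,
        proportion=proportion,
        proportion_se_ratio=prop_se_ratio,
        proportion_se_numerator=prop_se_num,
        proportion_ci=prop_ci,
        consistent=bool(consistent),
        flags=flags,
    )


def mediation_scan(
    total_effects: pd.DataFrame,
    step_a: pd.DataFrame,
    step_b: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan (exposure, mediator) pairs for mediation.

    ``total_effects`` has one row per exposure (columns exposure, beta, se,
    pval); ``step_a`` one row per (exposure, mediator) MR estimate; ``step_b``
    one row per mediator→outcome MR estimate (columns mediator, beta, se,
    pval). A pair yields a MediationResult only when both steps are
    significant at ``alpha``; failing pairs are returned separately with the
    failing step named.
    """
    totals = {r.exposure: Effect(r.beta, r.se, r.pval) for r in total_effects.itertuples()}
    b_map = {r.mediator: Effect(r.beta, r.se, r.pval) for r in step_b.itertuples()}
    results, failures = [], []
    for r in step_a.itertuples():
        if r.exposure not in totals:
            failures.append({"exposure": r.exposure, "mediator": r.mediator,
                             "failed_step": "no_total_effect"})
            continue
        a_eff = Effect(r.beta, r.se, r.pval)
        if a_eff.pval is None or a_eff.pval >= alpha:
            failures.append({"exposure": r.exposure, "mediator": r.mediator,
                             "failed_step": "step_a_not_significant"})
            continue
        b_eff = b_map.get(r.mediator)
        if b_eff is None or b_eff.pval is None or b_eff.pval >= alpha:
            failures.append({"exposure": r.exposure, "mediator": r.mediator,
                             "failed_step": "step_b_not_significant"})
            continue
        med = two_step_mediation(a_eff, b_eff, totals[r.exposure])
        results.append({
            "exposure": r.exposure,
            "mediator": r.mediator,
            "a": med.a.beta, "a_se": med.a.se,
            "b": med.b.beta, "b_se": med.b.se,
            "c": med.c.beta, "c_se": med.c.se,
            "indirect": med.indirect, "indirect_se": med.indirect_se,
            "indirect_ci_low": med.indirect_ci[0], "indirect_ci_high": med.indirect_ci[1],
            "direct": med.direct,
            "proportion": med.proportion,
            "proportion_ci_low": med.proportion_ci[0] if med.proportion_ci else None,
            "proportion_ci_high": med.proportion_ci[1] if med.proportion_ci else None,
            "consistent": med.consistent,
            "flags": ";".join(med.flags),
        })
    res = pd.DataFrame(results)
    if len(res):
        res = res.reindex(res["proportion"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return res, pd.DataFrame(failures, columns=["exposure", "mediator", "failed_step"])
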