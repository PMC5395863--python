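"""Per-study effect sizes and pooled meta-analysis estimates.

Implements the computational core needed to recompute a systematic review's
primary meta-analysis with the same summary measure and model as the original
analysis: risk ratio (RR), odds ratio (OR) and risk difference (RD) for
dichotomous outcomes, mean difference (MD) and standardized mean difference
(SMD, with the Hedges small-sample correction) for continuous outcomes;
fixed-effect and DerSimonian-Laird random-effects inverse-variance pooling;
and fixed-effect Mantel-Haenszel pooling with Greenland-Robins variances.

Ratio measures are analysed on the log scale and back-transformed for
reporting; difference measures are analysed on the identity scale.  All
confidence intervals are 95% normal-theory intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "SummaryMeasure",
    "PoolingModel",
    "PoolingMethod",
    "DichotomousArms",
    "ContinuousArms",
    "EffectEstimate",
    "PooledResult",
    "InputDataError",
    "effect_dichotomous",
    "effect_continuous",
    "study_effect",
    "pool",
    "pool_mh",
    "pool_review",
]

#: Normal quantile for two-sided 95% confidence intervals.
Z_95 = 1.959963984540054


class InputDataError(ValueError):
    """Raised when arm-level data violate its invariants."""


class SummaryMeasure(str, Enum):
    """Effect scale pooled across studies.

    RR and OR are analysed on the log scale (null value 1 on the natural
    scale); RD, MD and SMD are analysed on the identity scale (null value 0).
    """

    RR = "RR"
    OR = "OR"
    RD = "RD"
    MD = "MD"
    SMD = "SMD"

    @property
    def log_scale(self) -> bool:
        return self in (SummaryMeasure.RR, SummaryMeasure.OR)

    @property
    def analysis_scale(self) -> str:
        return "log" if self.log_scale else "identity"

    @property
    def null_value(self) -> float:
        """Null value on the natural (reported) scale."""
        return 1.0 if self.log_scale else 0.0

    @property
    def dichotomous(self) -> bool:
        return self in (SummaryMeasure.RR, SummaryMeasure.OR, SummaryMeasure.RD)


class PoolingModel(str, Enum):
    fixed = "fixed"
    random = "random"


class PoolingMethod(str, Enum):
    inverse_variance = "inverse_variance"
    mantel_haenszel = "mantel_haenszel"


@dataclass(frozen=True)
class DichotomousArms:
    """2x2 table for one study: events/total in treatment and control arms."""

    events_treatment: int
    total_treatment: int
    events_control: int
    total_control: int

    def __post_init__(self) -> None:
        for arm in ("treatment", "control"):
            e = getattr(self, f"events_{arm}")
            n = getattr(self, f"total_{arm}")
            if n <= 0:
                raise InputDataError(f"total_{arm} must be positive, got {n}")
            if e < 0 or e > n:
                raise InputDataError(
                    f"events_{arm}={e} must lie in [0, total_{arm}={n}]"
                )

    @property
    def n_total(self) -> int:
        return self.total_treatment + self.total_control


@dataclass(frozen=True)
class ContinuousArms:
    """Summary statistics (mean, sd, n) per arm for a continuous outcome."""

    mean_treatment: float
    sd_treatment: float
    n_treatment: int
    mean_control: float
    sd_control: float
    n_control: int

    def __post_init__(self) -> None:
        for arm in ("treatment", "control"):
            if getattr(self, f"sd_{arm}") <= 0:
                raise InputDataError(f"sd_{arm} must be positive")
            if getattr(self, f"n_{arm}") < 2:
                raise InputDataError(f"n_{arm} must be at least 2")

    @property
    def n_total(self) -> int:
        return self.n_treatment + self.n_control


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study effect on the analysis scale with its sampling variance."""

    value: float = math.nan
    variance: float = math.nan
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable and not self.variance > 0:
            raise InputDataError("estimable effect requires variance > 0")

    @staticmethod
    def not_estimable() -> "EffectEstimate":
        return EffectEstimate(math.nan, math.nan, estimable=False)


@dataclass(frozen=True)
class PooledResult:
    """A pooled estimate with 95% CI on the natural (reported) scale."""

    measure: SummaryMeasure
    model: PoolingModel
    method: PoolingMethod
    point: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_studies: int = 0
    n_participants: int = 0
    tau2: float = 0.0
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable:
            if not (self.ci_low <= self.point <= self.ci_high):
                raise InputDataError("CI must bracket the point estimate")
            if self.n_studies < 1:
                raise InputDataError("estimable result requires n_studies >= 1")

    @property
    def analysis_value(self) -> float:
        """Point estimate on the analysis scale (log for RR/OR)."""
        return math.log(self.point) if self.measure.log_scale else self.point

    @property
    def ci_width(self) -> float:
        """CI width on the natural scale (high - low, not on the log scale)."""
        return self.ci_high - self.ci_low

    def significant(self) -> bool:
        """True iff the 95% CI strictly excludes the measure's null value.

        A bound exactly on the null counts as not significant.
        """
        null = self.measure.null_value
        return self.ci_low > null or self.ci_high < null


# ---------------------------------------------------------------------------
# Per-study effects
# ---------------------------------------------------------------------------


def effect_dichotomous(
    arms: DichotomousArms, measure: SummaryMeasure
) -> EffectEstimate:
    """Effect estimate for a 2x2 table on the measure's analysis scale.

    RR and OR are returned as log effects with their large-sample variances.
    When any cell of the table is zero, 0.5 is added to all four cells
    (continuity correction) for RR/OR; when both arms have zero events the
    ratio measures are not estimable.  RD is the raw risk difference with
    the usual binomial variance; when an arm's variance contribution is
    degenerate (p-hat of 0 or 1) that term uses the shrunk proportion
    (e + 0.5) / (n + 1) so the variance stays positive.
    """
    if not measure.dichotomous:
        raise InputDataError(f"measure {measure.value} is not dichotomous")
    a, n1 = arms.events_treatment, arms.total_treatment
    c, n2 = arms.events_control, arms.total_control
    b, d = n1 - a, n2 - c

    if measure is SummaryMeasure.RD:
        value = a / n1 - c / n2
        var = 0.0
        for e, n in ((a, n1), (c, n2)):
            p = e / n
            if p == 0.0 or p == 1.0:
                p = (e + 0.5) / (n + 1)
            var += p * (1 - p) / n
        return EffectEstimate(value, var)

    if a == 0 and c == 0:
        return EffectEstimate.not_estimable()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        n1, n2 = n1 + 1, n2 + 1

    if measure is SummaryMeasure.RR:
        value = math.log((a / n1) / (c / n2))
        var = 1 / a - 1 / n1 + 1 / c - 1 / n2
    else:  # OR
        value = math.log((a * d) / (b * c))
        var = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectEstimate(value, var)


def effect_continuous(arms: ContinuousArms, measure: SummaryMeasure) -> EffectEstimate:
    """Mean difference or Hedges-corrected standardized mean difference.

    MD: difference in means, variance sd_t^2/n_t + sd_c^2/n_c.
    SMD: (mean_t - mean_c) / pooled sd, multiplied by the small-sample
    correction J = 1 - 3/(4N - 9); variance N/(n_t n_c) + g^2/(2(N - 3.94)).
    """
    if measure not in (SummaryMeasure.MD, SummaryMeasure.SMD):
        raise InputDataError(f"measure {measure.value} is not continuous")
    nt, nc = arms.n_treatment, arms.n_control
    diff = arms.mean_treatment - arms.mean_control

    if measure is SummaryMeasure.MD:
        var = arms.sd_treatment**2 / nt + arms.sd_control**2 / nc
        return EffectEstimate(diff, var)

    n_tot = nt + nc
    sp2 = ((nt - 1) * arms.sd_treatment**2 + (nc - 1) * arms.sd_control**2) / (
        n_tot - 2
    )
    j = 1 - 3 / (4 * n_tot - 9)
    g = j * diff / math.sqrt(sp2)
    var = n_tot / (nt * nc) + g**2 / (2 * (n_tot - 3.94))
    return EffectEstimate(g, var)


def study_effect(
    outcome: "DichotomousArms | ContinuousArms | EffectEstimate",
    measure: SummaryMeasure,
) -> EffectEstimate:
    """Dispatch on the outcome payload: arm data or a precomputed effect."""
    if isinstance(outcome, EffectEstimate):
        return outcome
    if isinstance(outcome, DichotomousArms):
        return effect_dichotomous(outcome, measure)
    if isinstance(outcome, ContinuousArms):
        return effect_continuous(outcome, measure)
    raise InputDataError(f"unsupported outcome payload {type(outcome).__name__}")


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def _finish(
    theta: float,
    se: float,
    measure: SummaryMeasure,
    model: PoolingModel,
    method: PoolingMethod,
    n_studies: int,
    n_participants: int,
    tau2: float = 0.0,
) -> PooledResult:
    lo, hi = theta - Z_95 * se, theta + Z_95 * se
    if measure.log_scale:
        theta, lo, hi = math.exp(theta), math.exp(lo), math.exp(hi)
    return PooledResult(
        measure=measure,
        model=model,
        method=method,
        point=theta,
        ci_low=lo,
        ci_high=hi,
        n_studies=n_studies,
        n_participants=n_participants,
        tau2=tau2,
    )


def _not_estimable(
    measure: SummaryMeasure, model: PoolingModel, method: PoolingMethod
) -> PooledResult:
    return PooledResult(measure=measure, model=model, method=method, estimable=False)


def pool(
    effects: list[EffectEstimate],
    model: PoolingModel,
    measure: SummaryMeasure,
    n_participants: int = 0,
    method: PoolingMethod = PoolingMethod.inverse_variance,
) -> PooledResult:
    """Inverse-variance pooled estimate (fixed or DerSimonian-Laird random).

    Non-estimable effects are dropped; with no estimable effect a flagged
    not-estimable result is returned rather than raising, so downstream
    impact classification can represent the all-studies-removed case.
    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w); random
    weights are 1/(v_i + tau^2).
    """
    if method is not PoolingMethod.inverse_variance:
        raise InputDataError("pool() is inverse-variance; use pool_mh for MH")
    est = [e for e in effects if e.estimable]
    if not est:
        return _not_estimable(measure, model, method)

    w = [1.0 / e.variance for e in est]
    sw = sum(w)
    theta_f = sum(wi * e.value for wi, e in zip(w, est)) / sw
    tau2 = 0.0
    if model is PoolingModel.random and len(est) > 1:
        q = sum(wi * (e.value - theta_f) ** 2 for wi, e in zip(w, est))
        c = sw - sum(wi**2 for wi in w) / sw
        if c > 0:
            tau2 = max(0.0, (q - (len(est) - 1)) / c)
    if model is PoolingModel.random:
        w = [1.0 / (e.variance + tau2) for e in est]
        sw = sum(w)
    theta = sum(wi * e.value for wi, e in zip(w, est)) / sw
    se = math.sqrt(1.0 / sw)
    return _finish(theta, se, measure, model, method, len(est), n_participants, tau2)


def pool_mh(
    studies: list[DichotomousArms],
    measure: SummaryMeasure,
    n_participants: int | None = None,
) -> PooledResult:
    """Fixed-effect Mantel-Haenszel pooled estimate for dichotomous data.

    Uses the Greenland-Robins variance estimators for log RR and log OR and
    the Greenland-Robins variance for the MH risk difference.  Strata with
    no information (e.g. double-zero tables for ratio measures) contribute
    nothing through the sums; no continuity correction is applied.  If every
    stratum is uninformative a flagged not-estimable result is returned.
    """
    if not measure.dichotomous:
        raise InputDataError(f"measure {measure.value} is not dichotomous")
    model, method = PoolingModel.fixed, PoolingMethod.mantel_haenszel
    if n_participants is None:
        n_participants = sum(s.n_total for s in studies)
    if not studies:
        return _not_estimable(measure, model, method)

    if measure is SummaryMeasure.RD:
        sw = sv = srd = 0.0
        for s in studies:
            a, n1, c, n2 = (
                s.events_treatment,
                s.total_treatment,
                s.events_control,
                s.total_control,
            )
            b, d, n = n1 - a, n2 - c, s.n_total
            wi = n1 * n2 / n
            sw += wi
            srd += wi * (a / n1 - c / n2)
            sv += (a * b * n2**3 + c * d * n1**3) / (n1 * n2 * n**2)
        if sw == 0 or sv == 0:
            return _not_estimable(measure, model, method)
        return _finish(
            srd / sw, math.sqrt(sv) / sw, measure, model, method,
            len(studies), n_participants,
        )

    s_r = s_s = 0.0
    if measure is SummaryMeasure.RR:
        s_p = 0.0
        for s in studies:
            a, n1, c, n2 = (
                s.events_treatment,
                s.total_treatment,
                s.events_control,
                s.total_control,
            )
            n = s.n_total
            s_r += a * n2 / n
            s_s += c * n1 / n
            s_p += (n1 * n2 * (a + c) - a * c * n) / n**2
        if s_r == 0 or s_s == 0:
            return _not_estimable(measure, model, method)
        theta = math.log(s_r / s_s)
        se = math.sqrt(s_p / (s_r * s_s))
    else:  # OR
        spr = spsqr = sqs = 0.0
        for s in studies:
            a, n1, c, n2 = (
                s.events_treatment,
                s.total_treatment,
                s.events_control,
                s.total_control,
            )
            b, d, n = n1 - a, n2 - c, s.n_total
            ri, si = a * d / n, b * c / n
            pi, qi = (a + d) / n, (b + c) / n
            s_r += ri
            s_s += si
            spr += pi * ri
            spsqr += pi * si + qi * ri
            sqs += qi * si
        if s_r == 0 or s_s == 0:
            return _not_estimable(measure, model, method)
        theta = math.log(s_r / s_s)
        se = math.sqrt(
            spr / (2 * s_r**2) + spsqr / (2 * s_r * s_s) + sqs / (2 * s_s**2)
        )
    n_est = sum(
        1
        for s in studies
        if not (s.events_treatment == 0 and s.events_control == 0)
    )
    return _finish(theta, se, measure, model, method, n_est, n_participants)


def pool_review(
    outcomes: list,
    measure: SummaryMeasure,
    model: PoolingModel,
    method: PoolingMethod,
    n_participants: int = 0,
) -> PooledResult:
    """Pool a list of study outcome payloads under a review's analysis choice.

    The Mantel-Haenszel method is defined for fixed-effect dichotomous
    analyses on raw 2x2 tables; a random-effects model combined with the MH
    method falls back to DerSimonian-Laird inverse-variance weighting (the
    behaviour of the standard review software), as does any study list that
    carries precomputed effects.
    """
    if not outcomes:
        return _not_estimable(measure, model, method)
    if (
        method is PoolingMethod.mantel_haenszel
        and model is PoolingModel.fixed
        and measure.dichotomous
        and all(isinstance(o, DichotomousArms) for o in outcomes)
    ):
        return pool_mh(outcomes, measure, n_participants)
    effects = [study_effect(o, measure) for o in outcomes]
    res = pool(effects, model, measure, n_participants)
    if method is PoolingMethod.mantel_haenszel:
        # keep the review's declared method in the record
        res = PooledResult(
            measure=res.measure,
            model=res.model,
            method=method,
            point=res.point,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            n_studies=res.n_studies,
            n_participants=res.n_participants,
            tau2=res.tau2,
            estimable=res.estimable,
        )
    return res
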