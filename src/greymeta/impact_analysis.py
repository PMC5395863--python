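"""Leave-one-study-type-out sensitivity re-analysis of a review corpus.

For each review and each grey-literature study type (non-English reports,
unpublished studies, dissertations) carried by at least one included study,
the primary meta-analysis is recomputed without that study type using the
same summary measure, model and pooling method.  The change is quantified as
the percent change in the point estimate and in the 95% CI width on the
natural (reported) scale, ignoring the direction of effect, and classified
as negligible (<5%), small (5-10%), moderate (11-20%), large (>20%) or
substantial (all studies removed, so no reduced estimate exists).  A change
in statistical significance (the CI crossing the measure's null value) is
flagged separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import TYPE_CHECKING, Optional

from .meta_engine import PooledResult, SummaryMeasure, pool_review

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_summary import ReviewRecord, StudyRecord

__all__ = [
    "StudyTypeLabel",
    "ImpactCategory",
    "SignificanceFlip",
    "ImpactMetrics",
    "exclude_by_type",
    "percent_lost",
    "percent_change_point",
    "percent_change_ci_width",
    "classify_change",
    "significance_flip",
    "significance_flip_ci",
    "change_metrics",
    "run_impact",
    "run_corpus_impact",
    "round_half_away",
]

logger = logging.getLogger("greymeta.impact")


class StudyTypeLabel(str, Enum):
    """Grey-literature study types; a study may carry any subset of them."""

    non_english = "non_english"
    unpublished = "unpublished"
    dissertation = "dissertation"


class ImpactCategory(str, Enum):
    negligible = "negligible"
    small = "small"
    moderate = "moderate"
    large = "large"
    #: reserved for the all-studies-removed case (no reduced estimate exists)
    substantial = "substantial"
    not_estimable = "not_estimable"


class SignificanceFlip(str, Enum):
    none = "none"
    lost = "lost"
    gained = "gained"
    undefined = "undefined"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ImpactMetrics:
    """With/without comparison for one review and one study type.

    Percentages are stored at full precision; reporting rounds to one
    decimal.  ``pct_change_point`` and ``pct_change_ci_width`` are ``None``
    when not estimable (zero denominator or no reduced estimate).
    """

    review_id: str
    label: StudyTypeLabel
    with_result: PooledResult
    without_result: PooledResult
    n_studies_with: int
    n_studies_without: int
    n_participants_with: int
    n_participants_without: int
    pct_studies_lost: float
    pct_participants_lost: float
    pct_change_point: Optional[float]
    pct_change_ci_width: Optional[float]
    category: ImpactCategory
    significance_flip: SignificanceFlip


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def exclude_by_type(review: "ReviewRecord", label: StudyTypeLabel) -> list:
    """Studies of the review not carrying the label, original order kept."""
    return [s for s in review.studies if label not in s.labels]


def percent_lost(count_with: int, count_without: int) -> Optional[float]:
    """Percent of studies (or participants) lost by the exclusion."""
    if count_without > count_with:
        raise ValueError("count_without must not exceed count_with")
    if count_with == 0:
        return None
    return 100.0 * (count_with - count_without) / count_with


def percent_change_point(
    with_point: float, without_point: float
) -> Optional[float]:
    """Magnitude-only percent change in the point estimate (natural scale).

    Direction of effect is ignored: only |without - with| / |with| matters,
    so a simultaneous sign flip of both estimates leaves the value unchanged.
    Not estimable when the reference estimate is exactly zero.
    """
    if with_point == 0:
        return None
    return 100.0 * abs(without_point - with_point) / abs(with_point)


def percent_change_ci_width(
    with_ci: tuple[float, float], without_ci: tuple[float, float]
) -> Optional[float]:
    """Percent change in CI width, widths taken on the natural scale."""
    w_with = with_ci[1] - with_ci[0]
    w_without = without_ci[1] - without_ci[0]
    if w_with < 0 or w_without < 0:
        raise ValueError("interval bounds must satisfy low <= high")
    if w_with == 0:
        return None
    return 100.0 * abs(w_without - w_with) / w_with


def classify_change(
    pct_change_point: Optional[float], all_removed: bool = False
) -> ImpactCategory:
    """Map a percent change in point estimate to the impact category.

    The percent change is rounded to the nearest integer (half away from
    zero) before mapping, which closes the gap between the "5-10%" and
    "11-20%" bands: 0-4 negligible, 5-10 small, 11-20 moderate, >=21 large.
    """
    if all_removed:
        return ImpactCategory.substantial
    if pct_change_point is None:
        return ImpactCategory.not_estimable
    pct = int(round_half_away(pct_change_point))
    if pct < 5:
        return ImpactCategory.negligible
    if pct <= 10:
        return ImpactCategory.small
    if pct <= 20:
        return ImpactCategory.moderate
    return ImpactCategory.large


def significance_flip_ci(
    with_ci: tuple[float, float],
    without_ci: tuple[float, float],
    null_value: float,
) -> SignificanceFlip:
    """Flip in statistical significance between two 95% CIs.

    A CI is significant iff it strictly excludes the null value; a bound
    exactly equal to the null counts as not significant.
    """

    def sig(ci: tuple[float, float]) -> bool:
        return ci[0] > null_value or ci[1] < null_value

    before, after = sig(with_ci), sig(without_ci)
    if before and not after:
        return SignificanceFlip.lost
    if after and not before:
        return SignificanceFlip.gained
    return SignificanceFlip.none


def significance_flip(
    with_result: PooledResult,
    without_result: PooledResult,
    measure: SummaryMeasure | None = None,
) -> SignificanceFlip:
    """Significance flip between two pooled results (undefined if either
    result is not estimable)."""
    if not (with_result.estimable and without_result.estimable):
        return SignificanceFlip.undefined
    measure = measure or with_result.measure
    return significance_flip_ci(
        (with_result.ci_low, with_result.ci_high),
        (without_result.ci_low, without_result.ci_high),
        measure.null_value,
    )


def change_metrics(
    with_point: float,
    with_ci: tuple[float, float],
    without_point: Optional[float],
    without_ci: Optional[tuple[float, float]],
    all_removed: bool = False,
) -> tuple[Optional[float], Optional[float], ImpactCategory]:
    """Estimate-pair mode: percent-change pair and category straight from two
    reported pooled estimates and CIs (no raw study data needed)."""
    if all_removed or without_point is None or without_ci is None:
        return None, None, classify_change(None, all_removed=True)
    pct_pt = percent_change_point(with_point, without_point)
    pct_ci = percent_change_ci_width(with_ci, without_ci)
    return pct_pt, pct_ci, classify_change(pct_pt)


# ---------------------------------------------------------------------------
# Full per-review procedure
# ---------------------------------------------------------------------------


def run_impact(
    review: "ReviewRecord", label: StudyTypeLabel
) -> Optional[ImpactMetrics]:
    """Re-analyse one review without one study type.

    Returns ``None`` (a skip marker, mirroring the analysis-set selection:
    only reviews with at least one study of the type are re-analysed) when
    no included study carries the label.
    """
    labeled = [s for s in review.studies if label in s.labels]
    if not labeled:
        return None
    kept = exclude_by_type(review, label)

    def _pool(studies: list) -> PooledResult:
        return pool_review(
            [s.outcome for s in studies],
            review.measure,
            review.model,
            review.method,
            n_participants=sum(s.n_participants for s in studies),
        )

    with_result = _pool(list(review.studies))
    without_result = _pool(kept)
    all_removed = len(kept) == 0

    n_with, n_without = len(review.studies), len(kept)
    p_with = sum(s.n_participants for s in review.studies)
    p_without = sum(s.n_participants for s in kept)

    if with_result.estimable and without_result.estimable:
        pct_pt = percent_change_point(with_result.point, without_result.point)
        pct_ci = percent_change_ci_width(
            (with_result.ci_low, with_result.ci_high),
            (without_result.ci_low, without_result.ci_high),
        )
    else:
        pct_pt = pct_ci = None
    category = classify_change(pct_pt, all_removed=all_removed)
    flip = significance_flip(with_result, without_result, review.measure)

    metrics = ImpactMetrics(
        review_id=review.review_id,
        label=label,
        with_result=with_result,
        without_result=without_result,
        n_studies_with=n_with,
        n_studies_without=n_without,
        n_participants_with=p_with,
        n_participants_without=p_without,
        pct_studies_lost=percent_lost(n_with, n_without),
        pct_participants_lost=percent_lost(p_with, p_without),
        pct_change_point=pct_pt,
        pct_change_ci_width=pct_ci,
        category=category,
        significance_flip=flip,
    )
    logger.info(
        "impact review=%s label=%s lost=%d/%d category=%s flip=%s",
        review.review_id,
        label.value,
        n_with - n_without,
        n_with,
        category.value,
        flip.value,
    )
    return metrics


def run_corpus_impact(
    corpus: list, labels: tuple[StudyTypeLabel, ...] = tuple(StudyTypeLabel)
) -> list[ImpactMetrics]:
    """Run the exclusion analysis for every review x label combination,
    skipping reviews that include no study of the given type."""
    out: list[ImpactMetrics] = []
    for review in corpus:
        for label in labels:
            m = run_impact(review, label)
            if m is not None:
                out.append(m)
    return out
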