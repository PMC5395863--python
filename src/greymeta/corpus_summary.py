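"""Corpus containers and searching/inclusion summaries.

A corpus is a list of :class:`ReviewRecord` objects, one per systematic
review, each holding the review's primary meta-analysis choice (summary
measure, model, pooling method), whether the review searched for each
grey-literature study type, and the included studies with their labels and
outcome payloads.

:func:`summarize` produces, per review group and overall and per study
type, the three denominators of interest: reviews that searched for the
type (% of all reviews), reviews that included it (% of those that
searched), and studies of the type (% of all included studies).
:func:`describe` gives median/IQR descriptives of the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import numpy as np
import pandas as pd

from .impact_analysis import StudyTypeLabel, round_half_away
from .meta_engine import (
    ContinuousArms,
    DichotomousArms,
    EffectEstimate,
    PoolingMethod,
    PoolingModel,
    SummaryMeasure,
)

__all__ = [
    "ReviewGroup",
    "StudyRecord",
    "ReviewRecord",
    "SummaryCell",
    "CorpusSummary",
    "CorpusDescriptives",
    "summarize",
    "describe",
    "OVERALL",
]

#: key used for the corpus-wide row of a summary
OVERALL = "total"

Outcome = Union[DichotomousArms, ContinuousArms, EffectEstimate]


class ReviewGroup(str, Enum):
    """Review group producing the systematic review."""

    ARI = "ARI"  # acute respiratory infections
    ID = "ID"  # infectious diseases
    DPLP = "DPLP"  # developmental, psychosocial and learning problems
    other = "other"


@dataclass(frozen=True)
class StudyRecord:
    """One study included in a review's primary meta-analysis."""

    study_id: str
    labels: frozenset
    n_participants: int
    outcome: Outcome
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass
class ReviewRecord:
    """One review's primary meta-analysis and its searching metadata."""

    review_id: str
    group: ReviewGroup
    measure: SummaryMeasure
    model: PoolingModel
    method: PoolingMethod
    studies: list
    searched: dict = field(default_factory=dict)
    year: Optional[int] = None
    title: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError(f"review {self.review_id} has no studies")
        # every label gets a searched flag; absent entries default to False
        self.searched = {
            label: bool(self.searched.get(label, False)) for label in StudyTypeLabel
        }

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_participants(self) -> int:
        return sum(s.n_participants for s in self.studies)

    def includes(self, label: StudyTypeLabel) -> bool:
        return any(label in s.labels for s in self.studies)

    def n_studies_of_type(self, label: StudyTypeLabel) -> int:
        return sum(1 for s in self.studies if label in s.labels)


@dataclass(frozen=True)
class SummaryCell:
    """Counts and percentages for one (group, study type) combination.

    ``pct_included`` uses the number of reviews that *searched* for the type
    as its denominator, not the number of reviews; ``pct_studies_of_type``
    uses all studies included across the group's reviews.
    """

    group: str
    label: StudyTypeLabel
    n_reviews: int
    n_searched: int
    pct_searched: Optional[float]
    n_included: int
    pct_included: Optional[float]
    n_studies_total: int
    n_studies_of_type: int
    pct_studies_of_type: Optional[float]


def _pct(num: int, den: int) -> Optional[float]:
    if den == 0:
        return None
    return round_half_away(100.0 * num / den, 1)


@dataclass
class CorpusSummary:
    """Summary cells per review group and overall, per study type."""

    cells: list

    def get(self, group: str, label: StudyTypeLabel) -> SummaryCell:
        for cell in self.cells:
            if cell.group == group and cell.label == label:
                return cell
        raise KeyError((group, label))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "group": c.group,
                    "study_type": c.label.value,
                    "n_reviews": c.n_reviews,
                    "n_searched": c.n_searched,
                    "pct_searched": c.pct_searched,
                    "n_included": c.n_included,
                    "pct_included": c.pct_included,
                    "n_studies_total": c.n_studies_total,
                    "n_studies_of_type": c.n_studies_of_type,
                    "pct_studies_of_type": c.pct_studies_of_type,
                }
            )
        return pd.DataFrame(rows)


def summarize(corpus: list) -> CorpusSummary:
    """Searching/inclusion counts and percentages per group and overall."""
    groups = sorted({r.group.value for r in corpus}) if corpus else []
    cells: list[SummaryCell] = []
    for label in StudyTypeLabel:
        for key in groups + [OVERALL]:
            reviews = (
                corpus
                if key == OVERALL
                else [r for r in corpus if r.group.value == key]
            )
            n_reviews = len(reviews)
            n_searched = sum(1 for r in reviews if r.searched[label])
            n_included = sum(
                1 for r in reviews if r.searched[label] and r.includes(label)
            )
            n_total = sum(r.n_studies for r in reviews)
            n_typed = sum(r.n_studies_of_type(label) for r in reviews)
            cells.append(
                SummaryCell(
                    group=key,
                    label=label,
                    n_reviews=n_reviews,
                    n_searched=n_searched,
                    pct_searched=_pct(n_searched, n_reviews),
                    n_included=n_included,
                    pct_included=_pct(n_included, n_searched),
                    n_studies_total=n_total,
                    n_studies_of_type=n_typed,
                    pct_studies_of_type=_pct(n_typed, n_total),
                )
            )
    return CorpusSummary(cells=cells)


@dataclass(frozen=True)
class CorpusDescriptives:
    median_year: Optional[float]
    iqr_year: Optional[tuple[float, float]]
    median_studies: float
    iqr_studies: tuple[float, float]
    median_participants: float
    iqr_participants: tuple[float, float]


def describe(corpus: list) -> CorpusDescriptives:
    """Median and IQR of publication year, studies and participants per
    review (inclusive linear-interpolation quartiles).  Year statistics are
    omitted when any review lacks a year."""
    if not corpus:
        raise ValueError("corpus must be non-empty")

    def med_iqr(values: list) -> tuple[float, tuple[float, float]]:
        q1, q2, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
        return float(q2), (float(q1), float(q3))

    years = [r.year for r in corpus]
    if any(y is None for y in years):
        my, iy = None, None
    else:
        my, iy = med_iqr(years)
    ms, is_ = med_iqr([r.n_studies for r in corpus])
    mp, ip = med_iqr([r.n_participants for r in corpus])
    return CorpusDescriptives(
        median_year=my,
        iqr_year=iy,
        median_studies=ms,
        iqr_studies=is_,
        median_participants=mp,
        iqr_participants=ip,
    )
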