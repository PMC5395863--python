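import pytest

from greymeta import (
    DichotomousArms,
    EffectEstimate,
    PoolingMethod,
    PoolingModel,
    ReviewGroup,
    ReviewRecord,
    StudyRecord,
    StudyTypeLabel,
    SummaryMeasure,
)


def make_study(study_id, outcome, labels=(), n_participants=None):
    if n_participants is None:
        n_participants = getattr(outcome, "n_total", 100)
    return StudyRecord(
        study_id=study_id,
        labels=frozenset(labels),
        n_participants=n_participants,
        outcome=outcome,
    )


def make_review(
    review_id,
    studies,
    measure=SummaryMeasure.RR,
    model=PoolingModel.fixed,
    method=PoolingMethod.inverse_variance,
    group=ReviewGroup.ARI,
    searched=None,
    year=None,
):
    return ReviewRecord(
        review_id=review_id,
        group=group,
        measure=measure,
        model=model,
        method=method,
        studies=studies,
        searched=searched or {label: True for label in StudyTypeLabel},
        year=year,
    )


@pytest.fixture
def three_study_review():
    """3-study dichotomous review; the second study is non-English."""
    studies = [
        make_study("S1", DichotomousArms(10, 50, 15, 50)),
        make_study("S2", DichotomousArms(8, 40, 12, 40), labels=[StudyTypeLabel.non_english]),
        make_study("S3", DichotomousArms(20, 100, 25, 100)),
    ]
    return make_review("R1", studies)


@pytest.fixture
def effect_review():
    """Review carrying precomputed per-study effects (identity scale)."""
    studies = [
        make_study("S1", EffectEstimate(0.2, 0.04), n_participants=60),
        make_study("S2", EffectEstimate(0.5, 0.09), labels=[StudyTypeLabel.unpublished], n_participants=40),
        make_study("S3", EffectEstimate(0.3, 0.01), n_participants=200),
    ]
    return make_review("R2", studies, measure=SummaryMeasure.MD)
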