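"""Effect-size formulas and pooling against hand-computed oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greymeta import (
    ContinuousArms,
    DichotomousArms,
    EffectEstimate,
    InputDataError,
    PoolingMethod,
    PoolingModel,
    SummaryMeasure,
    effect_continuous,
    effect_dichotomous,
    pool,
    pool_mh,
    pool_review,
)

Z = 1.959963984540054


class TestDichotomousEffects:
    def test_symmetric_table_gives_null_log_risk_ratio(self):
        e = effect_dichotomous(DichotomousArms(5, 10, 5, 10), SummaryMeasure.RR)
        assert e.value == pytest.approx(0.0)
        # hand formula: 1/5 - 1/10 + 1/5 - 1/10
        assert e.variance == pytest.approx(0.2)

    def test_zero_cell_triggers_half_correction_on_all_cells(self):
        e = effect_dichotomous(DichotomousArms(0, 10, 5, 10), SummaryMeasure.RR)
        # (0.5/10.5)/(5.5/10.5) = 0.5/5.5
        assert math.exp(e.value) == pytest.approx(0.5 / 5.5)

    def test_double_zero_ratio_not_estimable_but_rd_is_null(self):
        arms = DichotomousArms(0, 10, 0, 10)
        assert not effect_dichotomous(arms, SummaryMeasure.OR).estimable
        assert not effect_dichotomous(arms, SummaryMeasure.RR).estimable
        rd = effect_dichotomous(arms, SummaryMeasure.RD)
        assert rd.estimable and rd.value == 0.0 and rd.variance > 0

    def test_odds_ratio_hand_formula(self):
        e = effect_dichotomous(DichotomousArms(10, 40, 5, 40), SummaryMeasure.OR)
        assert e.value == pytest.approx(math.log((10 * 35) / (30 * 5)))
        assert e.variance == pytest.approx(1 / 10 + 1 / 30 + 1 / 5 + 1 / 35)

    def test_risk_difference_hand_formula(self):
        e = effect_dichotomous(DichotomousArms(10, 40, 5, 40), SummaryMeasure.RD)
        assert e.value == pytest.approx(0.25 - 0.125)
        assert e.variance == pytest.approx(
            0.25 * 0.75 / 40 + 0.125 * 0.875 / 40
        )

    def test_invalid_counts_raise(self):
        with pytest.raises(InputDataError):
            DichotomousArms(5, 4, 1, 10)
        with pytest.raises(InputDataError):
            DichotomousArms(-1, 10, 1, 10)
        with pytest.raises(InputDataError):
            DichotomousArms(1, 10, 1, 0)


class TestContinuousEffects:
    def test_identical_arms_give_zero_mean_difference(self):
        arms = ContinuousArms(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert effect_continuous(arms, SummaryMeasure.MD).value == 0.0

    def test_mean_difference_hand_formula(self):
        arms = ContinuousArms(10.0, 2.0, 20, 8.0, 2.0, 20)
        e = effect_continuous(arms, SummaryMeasure.MD)
        assert e.value == pytest.approx(2.0)
        assert e.variance == pytest.approx(4 / 20 + 4 / 20)

    def test_smd_is_unit_difference_times_hedges_factor(self):
        # mean difference 2, both sds 2 -> raw standardized difference 1.0
        arms = ContinuousArms(10.0, 2.0, 20, 8.0, 2.0, 20)
        e = effect_continuous(arms, SummaryMeasure.SMD)
        j = 1 - 3 / (4 * 40 - 9)
        assert e.value == pytest.approx(1.0 * j)

    def test_invalid_arms_raise(self):
        with pytest.raises(InputDataError):
            ContinuousArms(1.0, 0.0, 10, 0.0, 1.0, 10)
        with pytest.raises(InputDataError):
            ContinuousArms(1.0, 1.0, 1, 0.0, 1.0, 10)


class TestInverseVariancePooling:
    def test_single_effect_is_identity(self):
        e = EffectEstimate(0.4, 0.09)
        r = pool([e], PoolingModel.fixed, SummaryMeasure.MD)
        assert r.point == pytest.approx(0.4)
        assert r.ci_low == pytest.approx(0.4 - Z * 0.3)
        assert r.n_studies == 1

    def test_two_effect_hand_arithmetic(self):
        effects = [EffectEstimate(0.0, 1.0), EffectEstimate(1.0, 1.0)]
        r = pool(effects, PoolingModel.fixed, SummaryMeasure.MD)
        assert r.point == pytest.approx(0.5)
        assert r.ci_high == pytest.approx(0.5 + Z * math.sqrt(0.5))

    def test_identical_effects_give_zero_tau2_and_fixed_equals_random(self):
        effects = [EffectEstimate(0.3, 0.2)] * 4
        rf = pool(effects, PoolingModel.fixed, SummaryMeasure.MD)
        rr = pool(effects, PoolingModel.random, SummaryMeasure.MD)
        assert rr.tau2 == 0.0
        assert rr.point == pytest.approx(rf.point)
        assert rr.ci_low == pytest.approx(rf.ci_low)

    def test_log_scale_back_transform_keeps_ci_ordering(self):
        effects = [EffectEstimate(0.1, 0.05), EffectEstimate(-0.3, 0.1)]
        r = pool(effects, PoolingModel.random, SummaryMeasure.RR)
        assert r.ci_low <= r.point <= r.ci_high
        assert r.point > 0

    def test_empty_list_flags_not_estimable(self):
        r = pool([], PoolingModel.fixed, SummaryMeasure.RR)
        assert not r.estimable
        r2 = pool([EffectEstimate.not_estimable()], PoolingModel.fixed, SummaryMeasure.RR)
        assert not r2.estimable

    def test_replication_shrinks_ci_and_keeps_point(self):
        e = EffectEstimate(0.25, 0.04)
        r1 = pool([e], PoolingModel.fixed, SummaryMeasure.MD)
        r5 = pool([e] * 5, PoolingModel.fixed, SummaryMeasure.MD)
        assert r5.point == pytest.approx(r1.point)
        assert r5.ci_width < r1.ci_width

    def test_adding_larger_effect_moves_fixed_point_toward_it(self):
        effects = [EffectEstimate(0.1, 0.3), EffectEstimate(0.2, 0.5)]
        base = pool(effects, PoolingModel.fixed, SummaryMeasure.MD).point
        grown = pool(
            effects + [EffectEstimate(1.0, 0.4)],
            PoolingModel.fixed,
            SummaryMeasure.MD,
        ).point
        assert base < grown < 1.0

    def test_dersimonian_laird_tau2_hand_formula(self):
        effects = [
            EffectEstimate(0.0, 0.1),
            EffectEstimate(0.8, 0.2),
            EffectEstimate(-0.4, 0.4),
        ]
        w = np.array([10.0, 5.0, 2.5])
        y = np.array([0.0, 0.8, -0.4])
        theta_f = (w * y).sum() / w.sum()
        q = (w * (y - theta_f) ** 2).sum()
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - 2) / c)
        r = pool(effects, PoolingModel.random, SummaryMeasure.MD)
        assert r.tau2 == pytest.approx(tau2, rel=1e-12)
        wr = 1 / (np.array([0.1, 0.2, 0.4]) + tau2)
        assert r.point == pytest.approx((wr * y).sum() / wr.sum(), rel=1e-12)


class TestMantelHaenszel:
    def test_single_study_equals_study_effect(self):
        arms = DichotomousArms(12, 50, 8, 45)
        r = pool_mh([arms], SummaryMeasure.RR)
        assert math.log(r.point) == pytest.approx(math.log((12 / 50) / (8 / 45)))

    def test_two_identical_studies_replicate_single_point(self):
        arms = DichotomousArms(12, 50, 8, 45)
        r1 = pool_mh([arms], SummaryMeasure.OR)
        r2 = pool_mh([arms, arms], SummaryMeasure.OR)
        assert r2.point == pytest.approx(r1.point)
        assert r2.ci_width < r1.ci_width

    def test_two_stratum_toy_table_matches_direct_sums(self):
        s1, s2 = DichotomousArms(4, 10, 2, 12), DichotomousArms(6, 20, 9, 18)
        # direct evaluation of the MH sums for the risk ratio
        num = 4 * 12 / 22 + 6 * 18 / 38
        den = 2 * 10 / 22 + 9 * 20 / 38
        r = pool_mh([s1, s2], SummaryMeasure.RR)
        assert r.point == pytest.approx(num / den, rel=1e-12)

    def test_rd_weights_are_mh_weights(self):
        s1, s2 = DichotomousArms(4, 10, 2, 12), DichotomousArms(6, 20, 9, 18)
        w1, w2 = 10 * 12 / 22, 20 * 18 / 38
        expect = (w1 * (0.4 - 2 / 12) + w2 * (0.3 - 0.5)) / (w1 + w2)
        r = pool_mh([s1, s2], SummaryMeasure.RD)
        assert r.point == pytest.approx(expect, rel=1e-12)

    def test_all_zero_weights_not_estimable(self):
        arms = DichotomousArms(0, 10, 0, 12)
        assert not pool_mh([arms], SummaryMeasure.RR).estimable

    def test_pool_review_mh_random_falls_back_to_inverse_variance(self):
        studies = [DichotomousArms(4, 10, 2, 12), DichotomousArms(6, 20, 9, 18)]
        r = pool_review(
            studies,
            SummaryMeasure.RR,
            PoolingModel.random,
            PoolingMethod.mantel_haenszel,
        )
        iv = pool_review(
            studies,
            SummaryMeasure.RR,
            PoolingModel.random,
            PoolingMethod.inverse_variance,
        )
        assert r.point == pytest.approx(iv.point)
        assert r.method is PoolingMethod.mantel_haenszel


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(
            st.floats(-2, 2, allow_nan=False),
            st.floats(0.01, 2.0, allow_nan=False),
        ),
        min_size=1,
        max_size=5,
    )
)
def test_fixed_effect_matches_weighted_mean_oracle(pairs):
    """Inverse-variance fixed pooling equals the brute-force weighted mean."""
    effects = [EffectEstimate(v, var) for v, var in pairs]
    num = sum(v / var for v, var in pairs)
    den = sum(1 / var for v, var in pairs)
    r = pool(effects, PoolingModel.fixed, SummaryMeasure.MD)
    assert r.point == pytest.approx(num / den, rel=1e-10, abs=1e-12)
    assert r.ci_width == pytest.approx(2 * Z / math.sqrt(den), rel=1e-10)
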