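"""The deterministic growth equations: forward curve, inversion, juvenile
weight-age relation and cross-curve bias structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lensage import (
    GrowthCurveParams,
    JuvenileGrowthParams,
    age_bias_table,
    age_from_ldw,
    age_from_weight,
    predict_ldw,
    predict_log_ldw,
)


class TestPredictLdw:
    @pytest.mark.parametrize(
        "a,b,c,age,expected",
        [
            (240.0, 64.9, 32.0, 180.0, 118.59849181014445),  # 240*10^(-64.9/212)
            (273.0, 64.9, 32.0, 0.0, 2.558807688853883),  # 273*10^(-64.9/32)
        ],
    )
    def test_point_values(self, a, b, c, age, expected):
        assert predict_ldw(GrowthCurveParams(a, b, c), age) == pytest.approx(
            expected, rel=1e-12
        )

    def test_asymptote_is_the_large_age_limit(self, oca):
        assert predict_ldw(oca, 1e12) == pytest.approx(oca.a, rel=1e-9)
        ages = np.linspace(17, 1392, 200)
        assert np.all(predict_ldw(oca, ages) < oca.a)

    def test_monotone_in_age_and_parameters(self):
        ages = np.linspace(17, 1392, 300)
        base = GrowthCurveParams(240, 64.9, 32)
        ldw = predict_ldw(base, ages)
        assert np.all(np.diff(ldw) > 0)  # increasing in age
        bigger_a = predict_ldw(GrowthCurveParams(260, 64.9, 32), ages)
        assert np.all(bigger_a > ldw)  # increasing in a
        bigger_b = predict_ldw(GrowthCurveParams(240, 80.0, 32), ages)
        assert np.all(bigger_b < ldw)  # decreasing in b

    def test_nonpositive_elapsed_time_rejected(self):
        with pytest.raises(ValueError, match="age \\+ c"):
            predict_ldw(GrowthCurveParams(240, 64.9, 0.0), 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurveParams(-1, 64.9, 32)
        with pytest.raises(ValueError):
            GrowthCurveParams(240, 0, 32)
        with pytest.raises(ValueError):
            GrowthCurveParams(240, 64.9, -1)


class TestPredictLogLdw:
    def test_log_of_point_value(self):
        p = GrowthCurveParams(240, 64.9, 32)
        assert predict_log_ldw(p, 180.0) == pytest.approx(2.074079166239908, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.floats(1, 500),
        b=st.floats(1, 200),
        age=st.floats(1, 2000),
    )
    def test_round_trip_with_linear_form(self, a, b, age):
        p = GrowthCurveParams(a, b, 32.0)
        assert 10 ** predict_log_ldw(p, age) == pytest.approx(
            predict_ldw(p, age), rel=1e-12
        )

    def test_zero_growth_rate_limit_is_log_asymptote(self):
        p = GrowthCurveParams(100, 1e-12, 32.0)
        assert predict_log_ldw(p, 500.0) == pytest.approx(2.0, abs=1e-9)


class TestAgeFromLdw:
    def test_inverts_the_point_example(self, oca):
        assert age_from_ldw(oca, 118.59849181014445) == pytest.approx(180.0, abs=1e-9)

    def test_round_trip_over_study_range(self, oca, occ):
        for p in (oca, occ):
            for age in np.linspace(17, 1392, 120):
                assert age_from_ldw(p, predict_ldw(p, age)) == pytest.approx(
                    age, abs=1e-6
                )

    def test_asymptote_and_nonpositive_weights_rejected(self, oca):
        with pytest.raises(ValueError, match="asymptote"):
            age_from_ldw(oca, oca.a)
        with pytest.raises(ValueError, match="asymptote"):
            age_from_ldw(oca, oca.a + 5)
        with pytest.raises(ValueError, match="> 0"):
            age_from_ldw(oca, 0.0)


class TestAgeFromWeight:
    def test_weaning_weight_gives_weaning_age(self):
        res = age_from_weight(JuvenileGrowthParams(), 200.0)
        assert res.age_days == pytest.approx(21.0)
        assert res.estimated and not res.below_weaning

    def test_linear_growth_point(self):
        # 21 + (493.1 - 200)/9.77 = 51.0
        assert age_from_weight(JuvenileGrowthParams(), 493.1).age_days == pytest.approx(
            51.0, abs=1e-9
        )

    def test_cap_refused(self):
        with pytest.raises(ValueError, match="cap"):
            age_from_weight(JuvenileGrowthParams(), 500.0)

    def test_below_weaning_flagged(self):
        with pytest.warns(UserWarning, match="below the weaning weight"):
            res = age_from_weight(JuvenileGrowthParams(), 150.0)
        assert res.below_weaning and res.age_days < 21.0

    def test_affine_in_weight_with_slope_1_over_r(self):
        jp = JuvenileGrowthParams()
        a1 = age_from_weight(jp, 250.0).age_days
        a2 = age_from_weight(jp, 350.0).age_days
        assert (a2 - a1) / 100.0 == pytest.approx(1.0 / jp.r, rel=1e-12)


class TestAgeBiasTable:
    def test_identity_curves_have_zero_bias(self, oca):
        tab = age_bias_table(oca, oca, [30, 180, 360, 720, 1392])
        assert np.allclose(tab["bias_days"], 0.0, atol=1e-9)

    def test_smaller_asymptote_lenses_underaged_by_larger_curve(self, oca, occ):
        # closed form: 64.9/log10(273/118.598...) - 32 - 180
        tab = age_bias_table(oca, occ, [180.0])
        assert tab["bias_days"].iloc[0] == pytest.approx(-32.7595666710, abs=1e-6)

    def test_swapped_curves_flip_the_bias_sign(self, oca, occ):
        ages = np.linspace(30, 1392, 50)
        under = age_bias_table(oca, occ, ages)["bias_days"].to_numpy()
        over = age_bias_table(occ, oca, ages)["bias_days"].to_numpy()
        both = np.isfinite(under) & np.isfinite(over)
        assert both.any()
        assert np.all(under[both] < 0) and np.all(over[both] > 0)

    def test_bias_magnitude_grows_with_age_for_larger_assumed_asymptote(
        self, oca, occ
    ):
        ages = np.linspace(30, 1392, 100)
        bias = age_bias_table(oca, occ, ages)["bias_days"].to_numpy()
        assert np.all(np.isfinite(bias))
        assert np.all(np.diff(np.abs(bias)) > 0)

    def test_uninvertible_rows_become_nan_not_errors(self, occ, oca):
        # Occ lenses older than ~? exceed the Oca asymptote of 240 mg
        tab = age_bias_table(occ, oca, [100.0, 5000.0])
        assert np.isfinite(tab["age_est_days"].iloc[0])
        assert np.isnan(tab["age_est_days"].iloc[1])
        assert list(tab.columns) == [
            "age_days",
            "ldw_true_mg",
            "age_est_days",
            "bias_days",
        ]
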