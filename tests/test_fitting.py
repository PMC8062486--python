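"""Constrained nonlinear least squares: exact recovery, grid-search
optimality, standard-error behaviour and constraint/RSS structure."""

import numpy as np
import pytest

from lensage import (
    OCA_IBERIAN,
    OCC_IBERIAN,
    FitSpec,
    GrowthCurveParams,
    ObservationSet,
    fit_curve,
    predict_ldw,
    standard_errors,
)
from .conftest import make_noiseless, make_noisy

AGES = [20, 35, 60, 90, 150, 250, 400, 600, 900, 1200, 1392, 45]


class TestExactRecovery:
    def test_single_group_noiseless(self, oca):
        data = make_noiseless({"Oca": oca}, AGES)
        fit = fit_curve(data, FitSpec(share_a=False, share_b=False))
        assert fit.converged
        assert fit.estimates["a_Oca"] == pytest.approx(240.0, rel=1e-6)
        assert fit.estimates["b_Oca"] == pytest.approx(64.9, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_two_group_constrained_noiseless(self, oca, occ, model4_spec):
        data = make_noiseless({"Occ": occ, "Oca": oca}, AGES)
        fit = fit_curve(data, model4_spec)
        assert fit.estimates["a_Occ"] == pytest.approx(273.0, rel=1e-6)
        assert fit.estimates["a_Oca"] == pytest.approx(240.0, rel=1e-6)
        assert fit.estimates["b"] == pytest.approx(64.9, rel=1e-6)

    def test_linear_and_log_scale_agree_on_noiseless_data(self, oca):
        data = make_noiseless({"Oca": oca}, AGES)
        lin = fit_curve(data, FitSpec(False, False, scale="linear"))
        log = fit_curve(data, FitSpec(False, False, scale="log"))
        for k in lin.estimates:
            assert lin.estimates[k] == pytest.approx(log.estimates[k], rel=1e-6)


class TestGridOracle:
    def test_optimum_beats_dense_grid(self, oca):
        """The NLS optimum's RSS is below every point of a 200x200 brute-force
        grid over (a, b)."""
        data = make_noisy({"Oca": oca}, AGES, sd=5.0, seed=7)
        fit = fit_curve(data, FitSpec(share_a=False, share_b=False))
        ages, y = data.ages(), data.ldw()
        a_grid = np.linspace(180, 320, 200)
        b_grid = np.linspace(40, 95, 200)
        pred = a_grid[:, None, None] * 10.0 ** (
            -b_grid[None, :, None] / (ages[None, None, :] + 32.0)
        )
        rss_grid = ((y[None, None, :] - pred) ** 2).sum(axis=2)
        assert fit.rss <= rss_grid.min() + 1e-9


class TestStandardErrors:
    def test_noiseless_fit_has_vanishing_ses(self, oca):
        data = make_noiseless({"Oca": oca}, AGES)
        fit = fit_curve(data, FitSpec(False, False))
        assert all(se < 1e-6 for se in fit.standard_errors.values())

    def test_doubling_noise_doubles_ses_in_expectation(self, oca):
        ratios = []
        for seed in range(200):
            rng_pair = []
            for sd in (5.0, 10.0):
                data = make_noisy({"Oca": oca}, AGES, sd=sd, seed=seed)
                fit = fit_curve(data, FitSpec(False, False))
                rng_pair.append(fit.standard_errors["a_Oca"])
            ratios.append(rng_pair[1] / rng_pair[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_se_shrinks_like_one_over_sqrt_n(self, oca):
        """Replicating a fixed noisy design k times scales SEs by ~1/sqrt(k)."""
        base = make_noisy({"Oca": oca}, AGES, sd=10.0, seed=3)
        ses = {}
        for k in (1, 4, 16):
            recs = tuple(
                r.__class__(
                    id=f"{r.id}-rep{j}",
                    group=r.group,
                    age_days=r.age_days,
                    ldw_mg=r.ldw_mg,
                )
                for j in range(k)
                for r in base.records
            )
            data = ObservationSet(records=recs, groups=base.groups)
            fit = fit_curve(data, FitSpec(False, False))
            ses[k] = fit.standard_errors["a_Oca"]
        assert ses[4] / ses[1] == pytest.approx(0.5, rel=0.15)
        assert ses[16] / ses[1] == pytest.approx(0.25, rel=0.15)

    def test_nonconverged_fit_refuses_ses(self, oca, model4_spec):
        data = make_noiseless({"Oca": oca, "Occ": OCC_IBERIAN}, AGES)
        fit = fit_curve(data, model4_spec)
        bad = fit.__class__(**{**fit.__dict__, "converged": False})
        with pytest.raises(ValueError, match="converged"):
            standard_errors(bad, data, model4_spec)


class TestConstraintStructure:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sharing_constraints_never_decrease_rss(self, oca, occ, seed):
        data = make_noisy({"Occ": occ, "Oca": oca}, AGES, sd=15.0, seed=seed)
        free = fit_curve(data, FitSpec(False, False)).rss
        assert fit_curve(data, FitSpec(True, False)).rss >= free - 1e-8
        assert fit_curve(data, FitSpec(False, True)).rss >= free - 1e-8
        assert fit_curve(data, FitSpec(True, True)).rss >= free - 1e-8

    def test_record_order_invariance(self, oca, occ, model4_spec):
        data = make_noisy({"Occ": occ, "Oca": oca}, AGES, sd=15.0, seed=5)
        rev = ObservationSet(records=data.records[::-1], groups=data.groups)
        f1, f2 = fit_curve(data, model4_spec), fit_curve(rev, model4_spec)
        for k in f1.estimates:
            assert f1.estimates[k] == pytest.approx(f2.estimates[k], rel=1e-8)

    def test_group_renaming_changes_only_key_names(self, oca, occ, model4_spec):
        d1 = make_noisy({"Occ": occ, "Oca": oca}, AGES, sd=15.0, seed=5)
        d2 = make_noisy({"north": occ, "south": oca}, AGES, sd=15.0, seed=5)
        f1, f2 = fit_curve(d1, model4_spec), fit_curve(d2, model4_spec)
        assert f1.estimates["a_Occ"] == pytest.approx(f2.estimates["a_north"], rel=1e-9)
        assert f1.estimates["a_Oca"] == pytest.approx(f2.estimates["a_south"], rel=1e-9)
        assert f1.estimates["b"] == pytest.approx(f2.estimates["b"], rel=1e-9)


class TestValidationAndErrors:
    def test_k_counts_residual_sd(self, oca, occ, study_dataset):
        # two groups: Model 1 -> 3, Models 3/4 -> 4, Model 2 -> 5
        for spec, k in [
            (FitSpec(True, True), 3),
            (FitSpec(False, True), 4),
            (FitSpec(True, False), 4),
            (FitSpec(False, False), 5),
        ]:
            assert fit_curve(study_dataset, spec).K == k

    def test_loglik_matches_gaussian_formula(self, study_dataset, model4_spec):
        fit = fit_curve(study_dataset, model4_spec)
        n, rss = fit.n, fit.rss
        expected = -n / 2 * (np.log(2 * np.pi) + np.log(rss / n) + 1)
        assert fit.loglik == pytest.approx(expected, rel=1e-12)

    def test_degenerate_designs_rejected(self, oca):
        same_age = make_noisy({"Oca": oca}, [100.0] * 12, sd=5.0, seed=0)
        with pytest.raises(ValueError, match="singular"):
            fit_curve(same_age, FitSpec(False, False))

    def test_too_few_observations_rejected(self, oca):
        data = make_noiseless({"Oca": oca}, [30, 60, 90, 400, 900])
        with pytest.raises(ValueError, match="at least 3 observations"):
            fit_curve(data, FitSpec(False, False))

    def test_custom_init_is_honoured_and_deterministic(self, oca):
        data = make_noisy({"Oca": oca}, AGES, sd=5.0, seed=11)
        spec = FitSpec(False, False)
        f1 = fit_curve(data, spec, init={"a_Oca": 300.0, "b_Oca": 80.0})
        f2 = fit_curve(data, spec)
        for k in f1.estimates:  # same optimum from different starts
            assert f1.estimates[k] == pytest.approx(f2.estimates[k], rel=1e-6)
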