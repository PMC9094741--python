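"""Regression, agreement, partial-correlation, and normality statistics."""

import numpy as np
import pytest

import epwv
from epwv.errors import (DegenerateInputError, InvalidInputError,
                         SingularDesignError, UndefinedCorrelationError)


class TestQuadraticModel:
    def test_exact_quadratic_fit(self):
        age = np.linspace(20, 80, 40)
        y = 2.0 + 0.01 * age + 0.001 * age**2
        res = epwv.quadratic_model(y, age)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.standardized_betas["age"] == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["age_sq"] == pytest.approx(0.001, abs=1e-9)

    def test_pure_noise_null_case(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 80, 10_000)
        y = rng.normal(size=10_000)
        res = epwv.quadratic_model(y, age)
        assert res.r_squared < 0.01

    def test_athletes_age_beta_dominates(self, presets):
        """Age is by far the strongest predictor of estimated PWV."""
        rng = np.random.default_rng(8)
        cohort = epwv.draw_cohort(presets["athletes"], seed=None, rng=rng)
        records = epwv.run_measurement_pipeline(cohort, rng, via_signals=False)
        res = epwv.quadratic_model(records["estimated_pwv"], records["age"],
                                   covariates=records[["map", "sex", "bmi"]])
        assert res.standardized_betas["age"] > 0.85
        assert res.standardized_betas["age"] > 4 * abs(res.standardized_betas["map"])
        assert res.r_squared >= 0.95

    def test_rank_deficiency_detected(self):
        age = np.linspace(20, 80, 30)
        with pytest.raises(SingularDesignError):
            epwv.quadratic_model(np.ones(30) + age * 0.01, age,
                                 covariates={"dup": age})

    def test_nested_models_never_lose_r_squared(self, presets):
        rng = np.random.default_rng(9)
        cohort = epwv.draw_cohort(presets["agbresa"], seed=None, rng=rng)
        records = epwv.run_measurement_pipeline(cohort, rng, via_signals=False)
        r2_age = epwv.r_squared_age_alone(records["estimated_pwv"], records["age"])
        r2_full = epwv.quadratic_model(
            records["estimated_pwv"], records["age"],
            covariates=records[["map", "sex", "bmi"]]).r_squared
        assert r2_full >= r2_age - 1e-12


class TestBlandAltman:
    def test_constant_offset_pairs(self):
        res = epwv.bland_altman([5, 6, 7], [4, 5, 6], [30, 40, 50])
        assert res.mean_difference == pytest.approx(1.0)
        assert res.sd_difference == pytest.approx(0.0)
        assert res.limits_of_agreement[0] == pytest.approx(1.0)
        assert res.limits_of_agreement[1] == pytest.approx(1.0)

    def test_identical_vectors(self):
        v = [4.1, 5.2, 6.3, 7.4]
        res = epwv.bland_altman(v, v, [30, 40, 50, 60])
        assert res.mean_difference == 0.0
        assert res.sd_difference == 0.0
        assert res.diff_vs_age_slope == 0.0

    def test_mean_difference_identity(self, presets):
        """mean_difference equals mean(est) - mean(meas) exactly."""
        rng = np.random.default_rng(10)
        est = rng.normal(5.8, 1.0, 50)
        meas = rng.normal(4.8, 0.6, 50)
        age = rng.uniform(24, 55, 50)
        res = epwv.bland_altman(est, meas, age)
        assert res.mean_difference == pytest.approx(est.mean() - meas.mean(),
                                                    abs=1e-12)
        lo, hi = res.limits_of_agreement
        assert lo == pytest.approx(res.mean_difference - 1.96 * res.sd_difference)
        assert hi == pytest.approx(res.mean_difference + 1.96 * res.sd_difference)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            epwv.bland_altman([1, 2, 3], [1, 2], [30, 40, 50])


class TestPartialCorrelation:
    def test_identical_vectors_give_r_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        age = rng.uniform(20, 60, 30)
        r, p = epwv.partial_correlation_given_age(x, x, age)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_pure_age_function_gives_r_near_zero(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(20, 60, 200)
        y_exact = 1.0 + 0.05 * age + 0.001 * age**2  # exactly explained by age
        x = rng.normal(size=200)
        with pytest.raises(UndefinedCorrelationError):
            epwv.partial_correlation_given_age(x, y_exact, age)
        # near-exact age function: residuals are independent noise, r ~ 0
        y = y_exact + rng.normal(0, 1e-4, 200)
        r, _ = epwv.partial_correlation_given_age(x, y, age)
        assert abs(r) < 0.2

    def test_conditionally_independent_centred_on_zero(self, presets, model):
        """Estimated and measured PWV share only age: mean partial r ~ 0."""
        rs = []
        for k in range(500):
            rng = np.random.default_rng([99, k])
            frame = epwv.draw_cohort(presets["agbresa"], seed=None, rng=rng).frame
            core = epwv.surrogate_estimated_pwv_core(
                frame["entered_age"].to_numpy(), frame["map"].to_numpy(), model)
            est = core + rng.normal(0, model.sigma_b, 24) \
                + rng.normal(0, model.sigma_r / np.sqrt(3), 24)
            r, _ = epwv.partial_correlation_given_age(
                est, frame["true_pwv"].to_numpy(), frame["age"].to_numpy())
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_small_n_rejected(self):
        with pytest.raises(InvalidInputError):
            epwv.partial_correlation_given_age([1, 2], [3, 4], [5, 6])


class TestNormality:
    def test_normal_sample_passes_in_most_seeds(self):
        flags = []
        for s in range(40):
            x = np.random.default_rng(s).normal(size=10_000)
            flags.append(epwv.ks_normality(x)["normal_flag"])
        assert np.mean(flags) >= 0.9

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(3).exponential(size=10_000)
        res = epwv.ks_normality(x)
        assert not res["normal_flag"]
        assert 0.0 <= res["statistic"] <= 1.0

    def test_plain_ks_variant_available(self):
        x = np.random.default_rng(4).normal(size=500)
        res = epwv.ks_normality(x, lilliefors_correction=False)
        assert 0.0 <= res["statistic"] <= 1.0

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateInputError):
            epwv.ks_normality(np.ones(100))
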