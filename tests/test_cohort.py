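"""Cohort generator, device surrogate, and calibration properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epwv
from epwv.cohort import (CALIBRATION_ANCHORS, _age_moments, age_distribution,
                         map_intercept)
from epwv.errors import ConfigError, InvalidInputError


class TestMapFromCuff:
    @pytest.mark.parametrize("sbp,dbp,expected", [
        (125, 70, 88.3333), (128, 78, 94.6667), (120, 90, 100.0)])
    def test_cuff_convention(self, sbp, dbp, expected):
        assert epwv.map_from_cuff(sbp, dbp) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("sbp,dbp", [(90, 90), (80, 90), (100, 0), (0, -10)])
    def test_degenerate_pressures_rejected(self, sbp, dbp):
        with pytest.raises(InvalidInputError):
            epwv.map_from_cuff(sbp, dbp)

    @given(dbp=st.floats(40, 120), pp=st.floats(1, 100))
    @settings(max_examples=50, derandomize=True)
    def test_map_strictly_between_dbp_and_sbp(self, dbp, pp):
        sbp = dbp + pp
        m = epwv.map_from_cuff(sbp, dbp)
        assert dbp < m < sbp


class TestSurrogate:
    def test_monotone_in_age_and_map(self, model):
        ages = np.arange(18.0, 101.0)
        vals = epwv.surrogate_estimated_pwv_core(ages, np.full_like(ages, 90.0))
        assert np.all(np.diff(vals) > 0)
        maps = np.linspace(50, 140, 91)
        vals_m = epwv.surrogate_estimated_pwv_core(np.full_like(maps, 50.0), maps)
        assert np.all(np.diff(vals_m) > 0)

    def test_vertex_below_adult_range(self, model):
        assert model.vertex_age < 18.0

    def test_map_sensitivity_is_linear(self, model):
        # one mmHg of MAP moves the output by exactly c3, at any age
        for age in (20, 40, 60, 80):
            d = (epwv.surrogate_estimated_pwv_core(age, 101.0)
                 - epwv.surrogate_estimated_pwv_core(age, 100.0))
            assert d == pytest.approx(model.c3, abs=1e-12)

    @pytest.mark.parametrize("age,map_mmhg", [(17, 90), (101, 90), (50, 45), (50, 150)])
    def test_domain_enforced(self, age, map_mmhg):
        with pytest.raises(InvalidInputError):
            epwv.surrogate_estimated_pwv_core(age, map_mmhg)

    def test_calibration_recovers_cohort_anchors(self, presets, model):
        # closed-form cohort expectations must equal the published anchors
        for name, key in [("agbresa", "est_mean_agbresa"),
                          ("athletes", "est_mean_athletes")]:
            rep = epwv.variance_decomposition_oracle(presets[name], model)
            assert rep.e_estimated == pytest.approx(CALIBRATION_ANCHORS[key], abs=1e-9)
        rep = epwv.variance_decomposition_oracle(presets["agbresa"], model)
        assert rep.r2_est_age == pytest.approx(
            CALIBRATION_ANCHORS["r2_est_age_agbresa"], abs=1e-9)
        assert rep.e_measured == pytest.approx(
            CALIBRATION_ANCHORS["meas_mean_agbresa"], abs=1e-9)
        assert rep.r2_meas_age == pytest.approx(
            CALIBRATION_ANCHORS["r2_meas_age_agbresa"], abs=1e-9)


class TestTruePwvModel:
    def test_noise_free_limit_is_linear(self, model):
        ages = np.array([30.0, 40.0, 50.0])
        v = epwv.true_pwv_model(ages, model=model, noise=False)
        slope = np.diff(v) / np.diff(ages)
        assert slope == pytest.approx([model.g1, model.g1])

    def test_cohort_expectation_matches_printed_mean(self, presets, model):
        m1 = _age_moments(presets["agbresa"])[0]
        assert model.g0 + model.g1 * m1 == pytest.approx(4.80, abs=1e-9)

    def test_r_squared_with_age_closed_form(self, presets, model):
        # Var decomposition: R^2 = g1^2 Var(a) / (g1^2 Var(a) + sigma_v^2)
        m1, m2, _, _ = _age_moments(presets["agbresa"])
        var_a = m2 - m1**2
        r2 = model.g1**2 * var_a / (model.g1**2 * var_a + model.sigma_v**2)
        assert r2 == pytest.approx(0.55, abs=1e-9)
        # Monte-Carlo agreement of the same quantity
        rng = np.random.default_rng(5)
        ages = age_distribution(presets["agbresa"]).rvs(size=100_000, random_state=rng)
        v = epwv.true_pwv_model(ages, rng=rng, model=model)
        mc = np.corrcoef(ages, v)[0, 1] ** 2
        assert mc == pytest.approx(r2, abs=0.02)


class TestDrawCohort:
    def test_preset_row_counts_and_ranges(self, presets):
        ath = epwv.draw_cohort(presets["athletes"], seed=3)
        assert len(ath) == 129
        assert abs(ath.frame["age"].mean() - 56) < 3
        agb = epwv.draw_cohort(presets["agbresa"], seed=3)
        assert len(agb) == 24
        assert agb.frame["age"].between(24, 55).all()

    def test_same_seed_reproduces_table(self, presets):
        a = epwv.draw_cohort(presets["agbresa"], seed=9).frame
        b = epwv.draw_cohort(presets["agbresa"], seed=9).frame
        assert a.equals(b)

    def test_subject_invariants_hold(self, presets):
        for name in ("athletes", "agbresa", "single_subject"):
            cohort = epwv.draw_cohort(presets[name], seed=5)
            for subject in cohort.subjects():
                subject.validate()  # raises on violation
            f = cohort.frame
            assert (f["map"] - (f["dbp"] + (f["sbp"] - f["dbp"]) / 3)).abs().max() < 1e-9

    def test_moment_recovery_over_replicates(self, presets):
        # means of age/sbp/dbp/bmi match preset means within 3 standard errors
        preset = presets["agbresa"]
        frames = [epwv.draw_cohort(preset, seed=s).frame for s in range(100)]
        pooled = {c: np.concatenate([f[c].to_numpy() for f in frames])
                  for c in ("age", "sbp", "dbp", "bmi")}
        for col, target in [("age", preset.age_mean), ("sbp", preset.sbp_mean),
                            ("dbp", preset.dbp_mean), ("bmi", preset.bmi_mean)]:
            x = pooled[col]
            se = x.std(ddof=1) / np.sqrt(len(x))
            assert abs(x.mean() - target) < 3 * se + 1e-9, col

    def test_invalid_preset_rejected(self):
        with pytest.raises(ConfigError):
            epwv.PresetSpec(name="custom", n=0, age_mean=30, age_sd=5,
                            age_range=(20, 40), sbp_mean=120, sbp_sd=10,
                            dbp_mean=80, dbp_sd=5, bmi_mean=24, bmi_sd=2,
                            sex_ratio=0.5, hr_mean=60, hr_sd=5)
        with pytest.raises(ConfigError):
            epwv.PresetSpec(name="custom", n=5, age_mean=30, age_sd=5,
                            age_range=(40, 20), sbp_mean=120, sbp_sd=10,
                            dbp_mean=80, dbp_sd=5, bmi_mean=24, bmi_sd=2,
                            sex_ratio=0.5, hr_mean=60, hr_sd=5)


class TestMonteCarloVsOracle:
    """Simulated R^2 values agree with the closed-form decomposition."""

    @pytest.mark.parametrize("name", ["agbresa", "athletes"])
    def test_r_squared_agreement_at_large_n(self, presets, model, name):
        oracle = epwv.variance_decomposition_oracle(presets[name], model)
        big = presets[name].with_n(100_000)
        rng = np.random.default_rng(17)
        frame = epwv.draw_cohort(big, seed=None, rng=rng).frame
        core = epwv.surrogate_estimated_pwv_core(
            frame["entered_age"].to_numpy(), frame["map"].to_numpy(), model)
        est = (core + rng.normal(0, model.sigma_b, len(frame))
               + rng.normal(0, model.sigma_r / np.sqrt(3), len(frame)))
        meas = frame["true_pwv"].to_numpy()
        age = frame["age"].to_numpy()
        assert epwv.r_squared_age_alone(est, age) == pytest.approx(
            oracle.r2_est_age, abs=0.02)
        assert epwv.r_squared_age_alone(meas, age) == pytest.approx(
            oracle.r2_meas_age, abs=0.02)
        assert np.corrcoef(est, meas)[0, 1] ** 2 == pytest.approx(
            oracle.r2_est_meas, abs=0.02)
        assert np.mean(est) - np.mean(meas) == pytest.approx(
            oracle.e_difference, abs=0.05)

    def test_degenerate_preset_unsupported(self, presets):
        with pytest.raises(epwv.UnsupportedModelError):
            epwv.variance_decomposition_oracle(presets["single_subject"])
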