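import numpy as np
import pytest

from hbref.continuous_centiles import (
    FPModel,
    _ols_deviance,
    fit_continuous_centile,
    fp_transform,
    select_fp_mean_model,
    test_sex_interaction as sex_interaction_lrt,
)
Z5 = -1.6448536269514722


def _fp1_model(age, powers=(0.0,)):
    scale = float(np.exp(np.mean(np.log(age))))
    return FPModel(len(powers), tuple(powers), np.zeros(1 + len(powers)),
                   False, False, 0.0, scale, np.asarray(age).size)


class TestFPTransform:
    def test_power_zero_is_log(self):
        cols = fp_transform([1.0], (0.0,), age_scale=1.0)
        assert cols[0, 0] == 0.0  # ln 1

    def test_identity_power(self):
        x = np.array([0.5, 2.0, 7.0])
        cols = fp_transform(x, (1.0,), age_scale=1.0)
        np.testing.assert_allclose(cols[:, 0], x)

    def test_repeated_power_adds_log_multiplied_term(self):
        e = np.e
        cols = fp_transform([e], (2.0, 2.0), age_scale=1.0)
        # x^2 and x^2 ln x at x = e: both e^2
        np.testing.assert_allclose(cols[0], [e ** 2, e ** 2])

    def test_repeated_log_power(self):
        cols = fp_transform([np.e ** 2], (0.0, 0.0), age_scale=1.0)
        np.testing.assert_allclose(cols[0], [2.0, 4.0])  # ln x, (ln x)^2

    def test_non_positive_age_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fp_transform([0.0, 1.0], (1.0,))

    def test_scale_invariance_of_predictions(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(0.5, 12, 500)
        hb = 100 + 8 * np.log(age) + rng.normal(0, 3, 500)
        m1 = select_fp_mean_model(age, hb)
        # predictions are invariant to the recorded preconditioning scale
        X = np.column_stack([np.ones(age.size),
                             fp_transform(age, m1.powers, m1.age_scale)])
        pred = X @ m1.coefficients
        Xu = np.column_stack([np.ones(age.size),
                              fp_transform(age, m1.powers, 1.0)])
        coef_u, *_ = np.linalg.lstsq(Xu, hb, rcond=None)
        np.testing.assert_allclose(pred, Xu @ coef_u, atol=1e-6)


class TestSelectFPMeanModel:
    def test_strong_log_signal_selects_power_zero(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(0.5, 66, 2000)
        hb = 100 + 8 * np.log(age) + rng.normal(0, 3, 2000)
        m = select_fp_mean_model(age, hb)
        assert (m.degree, m.powers) == (1, (0.0,))

    def test_pure_noise_selects_null(self):
        rng = np.random.default_rng(8)
        age = rng.uniform(0.5, 66, 2000)
        hb = 120 + rng.normal(0, 5, 2000)
        assert select_fp_mean_model(age, hb).degree == 0

    def test_deviance_nesting(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(0.5, 66, 800)
        hb = 110 + 0.2 * age + 5 * np.log(age) + rng.normal(0, 4, 800)
        scale = float(np.exp(np.mean(np.log(age))))

        def dev(powers):
            X = np.column_stack([np.ones(age.size),
                                 fp_transform(age, powers, scale)])
            return _ols_deviance(X, hb)[0]

        from hbref.continuous_centiles import FP_POWER_SET, _candidate_powers
        d_null = dev(())
        d_lin = dev((1.0,))
        d_fp1 = min(dev(pw) for pw in _candidate_powers(1))
        d_fp2 = min(dev(pw) for pw in _candidate_powers(2))
        assert d_null >= d_lin >= d_fp1 >= d_fp2

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="n >="):
            select_fp_mean_model(np.linspace(1, 10, 20), np.zeros(20))

    def test_sex_main_effect_always_included(self):
        rng = np.random.default_rng(6)
        n = 1000
        age = rng.uniform(18, 66, n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        hb = np.where(sex == "male", 150, 135) + rng.normal(0, 9, n)
        m = select_fp_mean_model(age, hb, sex)
        assert m.includes_sex_main
        assert m.degree == 0  # flat in age


class TestSexInteraction:
    def _data(self, rng, n=2000, diverge=0.0):
        age = rng.uniform(12, 66, n)
        sex = np.where(np.arange(n) % 2 == 0, "male", "female")
        ramp = np.clip((age - 12) / 6, 0, 1) * diverge
        hb = 120 + 3 * np.log(age) + np.where(sex == "male", ramp, 0) \
            + rng.normal(0, 9, n)
        return age, hb, sex

    def test_df_equals_number_of_fp_terms(self):
        rng = np.random.default_rng(9)
        age, hb, sex = self._data(rng)
        fp2 = _fp1_model(age, (0.5, 2.0))
        assert sex_interaction_lrt(age, hb, sex, fp2)["df"] == 2
        fp1 = _fp1_model(age, (0.0,))
        assert sex_interaction_lrt(age, hb, sex, fp1)["df"] == 1

    def test_divergent_curves_detected(self):
        rng = np.random.default_rng(10)
        age, hb, sex = self._data(rng, diverge=15.0)
        res = sex_interaction_lrt(age, hb, sex, _fp1_model(age))
        assert res["retain"] and res["p_value"] < 0.05

    def test_single_sex_rejected(self):
        rng = np.random.default_rng(11)
        age, hb, _ = self._data(rng)
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction_lrt(age, hb, np.repeat("female", age.size),
                                 _fp1_model(age))

    def test_null_model_rejected(self):
        rng = np.random.default_rng(12)
        age, hb, sex = self._data(rng)
        null = FPModel(0, (), np.zeros(2), True, False, 0.0, 1.0, age.size)
        with pytest.raises(ValueError, match="no age terms"):
            sex_interaction_lrt(age, hb, sex, null)


class TestFitContinuousCentile:
    def test_constant_data_flat_curve_zero_bands(self):
        age = np.linspace(1, 10, 100)
        curve = fit_continuous_centile(age, np.full(100, 120.0),
                                       fp=_fp1_model(age), B=10, seed=0)
        np.testing.assert_array_equal(curve.predicted_gL["all"], 120.0)
        np.testing.assert_array_equal(curve.band_lo_gL["all"],
                                      curve.band_hi_gL["all"])

    def test_matches_analytic_centile_curve(self):
        rng = np.random.default_rng(13)
        n, sigma = 5000, 5.0
        age = rng.uniform(0.5, 12, n)
        hb = 100 + 8 * np.log(age) + rng.normal(0, sigma, n)
        curve = fit_continuous_centile(age, hb, fp=_fp1_model(age), p=0.05,
                                       B=60, seed=1, grid_step_years=0.5)
        grid = curve.age_grid_years
        interior = (grid > 1.0) & (grid < 11.0)
        truth = 100 + 8 * np.log(grid) + Z5 * sigma
        err = np.abs(curve.predicted_gL["all"] - truth)
        assert err[interior].max() < 1.0

    def test_bands_contain_point_estimate(self):
        rng = np.random.default_rng(14)
        age = rng.uniform(0.5, 12, 400)
        hb = 100 + 8 * np.log(age) + rng.normal(0, 5, 400)
        curve = fit_continuous_centile(age, hb, fp=_fp1_model(age), B=80, seed=2)
        for s in curve.predicted_gL:
            assert np.all(curve.band_lo_gL[s] <= curve.predicted_gL[s])
            assert np.all(curve.predicted_gL[s] <= curve.band_hi_gL[s])

    def test_seeded_determinism(self):
        rng = np.random.default_rng(15)
        age = rng.uniform(0.5, 12, 300)
        hb = 100 + 8 * np.log(age) + rng.normal(0, 5, 300)
        a = fit_continuous_centile(age, hb, fp=_fp1_model(age), B=50, seed=7)
        b = fit_continuous_centile(age, hb, fp=_fp1_model(age), B=50, seed=7)
        np.testing.assert_array_equal(a.band_lo_gL["all"], b.band_lo_gL["all"])
        c = fit_continuous_centile(age, hb, fp=_fp1_model(age), B=50, seed=8)
        assert not np.array_equal(a.band_lo_gL["all"], c.band_lo_gL["all"])

    def test_fitted_check_loss_beats_truth_coefficients(self):
        rng = np.random.default_rng(16)
        n, sigma, p = 2000, 5.0, 0.05
        age = rng.uniform(0.5, 12, n)
        hb = 100 + 8 * np.log(age) + rng.normal(0, sigma, n)
        fp = _fp1_model(age)
        curve = fit_continuous_centile(age, hb, fp=fp, p=p, B=10, seed=3)
        X = np.column_stack([np.ones(n), fp_transform(age, fp.powers, fp.age_scale)])
        # truth curve in the same basis: 100 + 8 ln(age) + z sigma
        truth_coef = np.array([100 + Z5 * sigma + 8 * np.log(fp.age_scale), 8.0])
        grid_X = np.column_stack([
            np.ones(curve.age_grid_years.size),
            fp_transform(curve.age_grid_years, fp.powers, fp.age_scale),
        ])
        fitted_coef, *_ = np.linalg.lstsq(grid_X, curve.predicted_gL["all"],
                                          rcond=None)

        def qr_loss(coef):
            resid = hb - X @ coef
            return float(np.sum(resid * (p - (resid < 0))))
        assert qr_loss(fitted_coef) <= qr_loss(truth_coef) + 1e-6

    def test_bootstrap_band_pointwise_coverage(self):
        """Percentile bands cover the analytic centile curve at a midpoint in
        roughly 90% of seeded replicates (scaled-down replication study)."""
        R, cover, sigma = 150, 0, 5.0
        for r in range(R):
            rng = np.random.default_rng(7_000_000 + r)
            n = 300
            age = rng.uniform(0.5, 12, n)
            hb = 100 + 8 * np.log(age) + rng.normal(0, sigma, n)
            curve = fit_continuous_centile(age, hb, fp=_fp1_model(age), p=0.05,
                                           B=120, seed=r, grid_step_years=6.0)
            g = int(np.argmin(np.abs(curve.age_grid_years - 6.0)))
            truth = 100 + 8 * np.log(curve.age_grid_years[g]) + Z5 * sigma
            cover += (curve.band_lo_gL["all"][g] <= truth
                      <= curve.band_hi_gL["all"][g])
        assert 0.85 <= cover / R <= 0.95
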