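import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gelkit import thermoanalysis as th
from gelkit.structure_io import ThermoSeries
from gelkit.synthetic import make_bilinear_series, make_thermo_series


def brute_force_anova(x, y):
    """Explicit-sum-formula ANOVA, independent of the fitted-values route."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum() - sx * sx / n
    syy = (y * y).sum() - sy * sy / n
    sxy = (x * y).sum() - sx * sy / n
    sse_model = sxy * sxy / sxx
    sse_error = syy - sse_model
    f = (sse_model / 1.0) / (sse_error / (n - 2))
    return sse_model, sse_error, syy, f


class TestLinearFitAnova:
    def test_perfect_line(self):
        x = np.arange(5.0)
        fit = th.linear_fit_anova(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.sse_error == pytest.approx(0.0, abs=1e-20)
        assert fit.p_value == np.nextafter(0.0, 1.0)

    def test_matches_brute_force_formulas(self, rng):
        x = rng.uniform(0, 10, 42)
        y = rng.permutation(x)  # independent of x by construction
        fit = th.linear_fit_anova(x, y)
        sse_m, sse_e, sse_t, f = brute_force_anova(x, y)
        assert fit.sse_model == pytest.approx(sse_m, rel=1e-10)
        assert fit.sse_error == pytest.approx(sse_e, rel=1e-10)
        assert fit.sse_total == pytest.approx(sse_t, rel=1e-10)
        assert fit.f_value == pytest.approx(f, rel=1e-10)

    def test_matches_scipy_linregress(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        fit = th.linear_fit_anova(x, y)
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-12)
        assert fit.slope_se == pytest.approx(ref.stderr, rel=1e-10)
        assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_internal_identities(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 10, rng.integers(5, 50))
            y = rng.normal(0, 1, len(x))
            fit = th.linear_fit_anova(x, y)
            assert fit.sse_total == pytest.approx(
                fit.sse_model + fit.sse_error, rel=1e-12
            )
            assert fit.df_total == fit.df_model + fit.df_error
            assert fit.f_value == pytest.approx(
                fit.mse_model / fit.mse_error, rel=1e-12
            )
            assert 0 < fit.p_value <= 1

    def test_slope_recovery_figure_rate(self):
        # planted slope -6.0723e-4 with noise tuned so the slope SE ~ 8.8e-5;
        # the planted value must fall inside +/- 2 SE in >= 95% of replicates
        slope_true = -6.0723e-4
        T = np.linspace(273, 318, 42)
        sxx = np.sum((T - T.mean()) ** 2)
        sigma = 8.8e-5 * np.sqrt(sxx)
        hits = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            y = 0.28 + slope_true * T + rng.normal(0, sigma, 42)
            fit = th.linear_fit_anova(T, y)
            if abs(fit.slope - slope_true) <= 2 * fit.slope_se:
                hits += 1
        assert hits / 500 >= 0.95

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            th.linear_fit_anova([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            th.linear_fit_anova([1.0, 2.0], [1.0, 2.0])

    def test_confidence_band_narrower_than_prediction(self, rng):
        x = rng.uniform(0, 10, 20)
        y = x + rng.normal(0, 0.5, 20)
        fit = th.linear_fit_anova(x, y)
        x0 = np.linspace(0, 10, 5)
        clo, chi_ = fit.confidence_band(x0)
        plo, phi = fit.prediction_band(x0)
        assert np.all(plo < clo) and np.all(phi > chi_)

    def test_confidence_band_textbook_formula(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 2 * x + rng.normal(0, 1, 15)
        fit = th.linear_fit_anova(x, y)
        x0 = 4.2
        tcrit = stats.t.ppf(0.975, 13)
        half = tcrit * np.sqrt(
            fit.mse_error * (1 / 15 + (x0 - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2))
        )
        lo, hi = fit.confidence_band(x0)
        assert hi - lo == pytest.approx(2 * half, rel=1e-10)


class TestFSf:
    def test_table_values(self):
        # printed ANOVA p-values
        assert th.f_sf(47.56219, 1, 40) == pytest.approx(2.61381e-8, rel=5e-6)
        assert th.f_sf(9.68304, 1, 39) == pytest.approx(0.00347, abs=5e-6)
        assert th.f_sf(22.45198, 1, 40) == pytest.approx(2.71e-5, rel=5e-3)

    def test_zero_statistic(self):
        assert th.f_sf(0.0, 3, 7) == 1.0

    def test_matches_scipy(self, rng):
        for _ in range(50):
            f = float(rng.uniform(0, 20))
            d1 = int(rng.integers(1, 10))
            d2 = int(rng.integers(1, 60))
            assert th.f_sf(f, d1, d2) == pytest.approx(
                stats.f.sf(f, d1, d2), rel=1e-6
            )

    def test_t_squared_identity(self):
        # F(1, nu) upper tail at t^2 equals the two-sided t tail at |t|
        for t in (0.5, 1.0, 2.0, 3.5):
            for nu in (5, 20, 40):
                assert th.f_sf(t * t, 1, nu) == pytest.approx(
                    2 * stats.t.sf(t, nu), rel=1e-10
                )

    def test_invalid_df_errors(self):
        with pytest.raises(ValueError):
            th.f_sf(1.0, 0, 10)

    def test_total_sse_identity(self):
        assert th.total_sse(0.00211, 0.00177) == pytest.approx(0.00388, abs=1e-12)
        assert th.total_sse(0.54061, 2.17741) == pytest.approx(2.71802, abs=1e-12)


class TestExpansionCoefficient:
    def test_exact_exponential(self):
        series = make_thermo_series(alpha_p=8e-4, sigma=0.0)
        res = th.expansion_coefficient(series)
        assert res.alpha_p == pytest.approx(8e-4, abs=1e-12)

    def test_constant_density(self):
        T = np.linspace(273, 318, 10)
        series = ThermoSeries(pd.DataFrame({"temperature": T, "density": np.full(10, 1.3)}))
        assert th.expansion_coefficient(series).alpha_p == pytest.approx(0.0, abs=1e-15)

    def test_recovery_with_noise(self):
        alpha = 6.072e-4
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            series = make_thermo_series(alpha_p=alpha, sigma=0.002, seed=seed, n_points=42)
            res = th.expansion_coefficient(series)
            if abs(res.alpha_p - alpha) <= 2 * res.alpha_p_se:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_scale_invariance(self):
        series = make_thermo_series(alpha_p=5e-4, sigma=0.01, seed=3)
        scaled = ThermoSeries(
            series.data.assign(density=series.data["density"] * 7.5), units=series.units
        )
        a1 = th.expansion_coefficient(series).alpha_p
        a2 = th.expansion_coefficient(scaled).alpha_p
        assert a1 == pytest.approx(a2, rel=1e-12)


class TestGlassTransition:
    def test_exact_bilinear_recovery(self):
        T, y = make_bilinear_series(tg=424.7, sigma=0.0)
        fit = th.glass_transition(T, y)
        assert fit.breakpoint == pytest.approx(424.7, abs=0.1)
        assert fit.reliable

    def test_slopes_recovered(self):
        T, y = make_bilinear_series(tg=400.0, slope_lo=1e-4, slope_hi=9e-4, sigma=0.0)
        fit = th.glass_transition(T, y)
        assert fit.left_slope == pytest.approx(1e-4, rel=1e-3)
        assert fit.right_slope == pytest.approx(9e-4, rel=1e-3)

    def test_straight_line_flagged_unreliable(self):
        T = np.linspace(100, 600, 26)
        rng = np.random.default_rng(0)
        y = 0.7 + 4e-4 * T + rng.normal(0, 2e-3, 26)
        fit = th.glass_transition(T, y)
        assert not fit.reliable

    def test_breakpoint_strictly_interior(self):
        T, y = make_bilinear_series(tg=424.7, sigma=1e-3, seed=9)
        fit = th.glass_transition(T, y)
        assert T[0] < fit.breakpoint < T[-1]

    def test_noisy_recovery_median_error(self):
        errors = []
        for seed in range(200):
            T, y = make_bilinear_series(tg=424.7, sigma=2e-3, seed=seed)
            fit = th.glass_transition(T, y)
            errors.append(abs(fit.breakpoint - 424.7))
        assert np.median(errors) < 5.0

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            th.glass_transition([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_unsorted_temps_error(self):
        with pytest.raises(ValueError):
            th.glass_transition([1, 3, 2, 4, 5, 6, 7], np.arange(7.0))
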