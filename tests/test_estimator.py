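"""Least-squares fit, HAC covariance and Wald tests against brute-force oracles."""

import dataclasses
import warnings

import numpy as np
import pytest

import oracles
from itsapower import (
    ScenarioSpec,
    build_design,
    fit_itsa,
    fit_itsa_batch,
    fit_ols,
    newey_west_cov,
    simulate_series,
    wald_pvalue,
)


def series_with_outcome(n, idx, y):
    return dataclasses.replace(build_design(n, idx), outcome=np.asarray(y, float))


def random_series(rng, n=None):
    n = n if n is not None else int(rng.integers(6, 21))
    idx = int(rng.integers(2, n - 2))
    y = 10 + rng.normal(0, 1, n) + 0.3 * np.arange(n)
    return series_with_outcome(n, idx, y)


class TestFitOls:
    def test_noiseless_series_recovers_generating_coefficients(self, rng):
        spec = ScenarioSpec(12, intervention_index=6, sigma=1e-12,
                            level_change_pct=30.0)
        series = simulate_series(spec, rng)
        np.testing.assert_allclose(fit_ols(series), [10.0, 0.0, 3.0, 0.0], atol=1e-8)

    def test_matches_normal_equations_oracle_on_fixture(self):
        series = series_with_outcome(6, 3, [10.2, 9.8, 10.1, 12.9, 13.3, 13.0])
        expected = oracles.ols_normal_equations(series.design(), series.outcome)
        np.testing.assert_allclose(fit_ols(series), expected, rtol=1e-10)

    def test_constant_shift_moves_only_intercept(self, rng):
        series = random_series(rng)
        base = fit_ols(series)
        shifted = fit_ols(dataclasses.replace(series, outcome=series.outcome + 7.5))
        np.testing.assert_allclose(shifted - base, [7.5, 0, 0, 0], atol=1e-9)

    def test_degenerate_design_rejected(self):
        # intervention at the final period leaves X == XT: rank 3
        t = np.arange(6)
        x = (t >= 5).astype(int)
        from itsapower.dgp import SeriesData
        series = SeriesData(time_index=t, intervention_indicator=x, interaction=x,
                            outcome=np.ones(6))
        with pytest.raises(ValueError, match="degenerate"):
            fit_ols(series)


class TestNeweyWestCov:
    def test_lag0_equals_white_covariance(self, rng):
        series = random_series(rng, n=12)
        coef = fit_ols(series)
        resid = series.outcome - series.design() @ coef
        design = series.design()
        white = oracles.hac_double_loop(design, resid, lag=0)
        np.testing.assert_allclose(newey_west_cov(series, coef, 0), white, atol=1e-12)

    @pytest.mark.parametrize("lag", [0, 1, 2, 3])
    def test_matches_double_loop_oracle(self, lag, rng):
        series = random_series(rng, n=10)
        coef = fit_ols(series)
        resid = series.outcome - series.design() @ coef
        expected = oracles.hac_double_loop(series.design(), resid, lag)
        np.testing.assert_allclose(newey_west_cov(series, coef, lag), expected,
                                   atol=1e-10)

    def test_small_sample_factor_is_scalar_multiple(self, rng):
        series = random_series(rng, n=12)
        coef = fit_ols(series)
        plain = newey_west_cov(series, coef, 1)
        scaled = newey_west_cov(series, coef, 1, small_sample=True)
        np.testing.assert_allclose(scaled, plain * 12 / 8, rtol=1e-12)

    def test_zero_residuals_give_zero_matrix(self, rng):
        spec = ScenarioSpec(10, intervention_index=5, sigma=1e-14)
        series = simulate_series(spec, rng)
        coef = fit_ols(series)
        assert np.abs(newey_west_cov(series, coef, 1)).max() < 1e-20

    def test_symmetry_and_nonnegative_diagonal(self, rng):
        for _ in range(10):
            series = random_series(rng)
            cov = newey_west_cov(series, fit_ols(series), 1)
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            # diagonal entries can be exact zeros (e.g. an exactly
            # interpolated segment) up to rounding
            assert np.all(np.diag(cov) >= -1e-10 * np.abs(cov).max())

    def test_excessive_lag_rejected(self, rng):
        series = random_series(rng, n=8)
        with pytest.raises(ValueError):
            newey_west_cov(series, fit_ols(series), 8)


class TestWaldPvalue:
    def test_zero_coefficient_gives_p_one(self):
        assert wald_pvalue(0.0, 2.0) == 1.0
        assert wald_pvalue(0.0, 2.0, df_resid=10) == 1.0

    def test_sign_symmetry(self):
        assert wald_pvalue(1.3, 0.5, 8) == wald_pvalue(-1.3, 0.5, 8)
        assert wald_pvalue(1.3, 0.5) == wald_pvalue(-1.3, 0.5)

    @pytest.mark.parametrize("df", [4, 16, 96])
    def test_t_reference_matches_quadrature_oracle(self, df):
        p = wald_pvalue(1.96, 1.0, df_resid=df)
        assert p == pytest.approx(2 * oracles.t_sf_by_quadrature(1.96, df), rel=1e-8)

    def test_t_approaches_normal_for_large_df(self):
        assert wald_pvalue(1.96, 1.0, df_resid=10_000) == pytest.approx(0.05, abs=5e-4)

    def test_normal_reference_matches_erfc_oracle(self):
        p = wald_pvalue(2.5, 4.0)  # z = 1.25
        assert p == pytest.approx(2 * oracles.normal_sf_by_erfc(1.25), rel=1e-12)

    def test_zero_variance_is_degenerate_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert wald_pvalue(1.0, 0.0) == 0.0
        with pytest.warns(RuntimeWarning):
            assert wald_pvalue(0.0, 0.0) == 1.0


class TestFitItsa:
    def test_composition_equals_oracle_pipeline(self):
        """End-to-end agreement with normal equations + double loop + erfc."""
        spec = ScenarioSpec(30, intervention_index=15, rho=0.5,
                            trend_change_pct=50.0)
        series = simulate_series(spec, np.random.default_rng(123))
        fit = fit_itsa(series, lag=1)
        design = series.design()
        coef = oracles.ols_normal_equations(design, series.outcome)
        cov = oracles.hac_double_loop(design, series.outcome - design @ coef, 1)
        np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-8)
        np.testing.assert_allclose(fit.hac_covariance, cov, rtol=1e-8)
        z = abs(coef[3]) / np.sqrt(cov[3, 3])
        assert fit.p_trend == pytest.approx(2 * oracles.normal_sf_by_erfc(z), rel=1e-8)
        assert fit.df_resid == 26

    def test_oracle_equivalence_on_many_random_fixtures(self, rng):
        for _ in range(50):
            series = random_series(rng)
            lag = int(rng.integers(0, 4))
            fit = fit_itsa(series, lag=lag)
            design = series.design()
            coef = oracles.ols_normal_equations(design, series.outcome)
            cov = oracles.hac_double_loop(design, series.outcome - design @ coef, lag)
            np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(fit.hac_covariance, cov, rtol=1e-8, atol=1e-10)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        for use_t in (False, True):
            series = random_series(rng, n=18)
            res = sm.OLS(series.outcome, series.design()).fit(
                cov_type="HAC", cov_kwds={"maxlags": 1, "use_correction": False},
                use_t=use_t,
            )
            fit = fit_itsa(series, lag=1, use_t=use_t)
            np.testing.assert_allclose(fit.coefficients, res.params, rtol=1e-10)
            np.testing.assert_allclose(fit.hac_covariance, res.cov_params(),
                                       rtol=1e-10)
            if not use_t:  # statsmodels use_t uses df n-k as we do only for z
                assert fit.p_trend == pytest.approx(res.pvalues[3], rel=1e-10)

    def test_lag_changes_covariance_never_coefficients(self, rng):
        series = random_series(rng, n=16)
        fits = [fit_itsa(series, lag=lag) for lag in (0, 1, 3)]
        for fit in fits[1:]:
            np.testing.assert_array_equal(fit.coefficients, fits[0].coefficients)
        assert not np.allclose(fits[0].hac_covariance, fits[1].hac_covariance)

    def test_refit_is_deterministic(self, rng):
        series = random_series(rng)
        a, b = fit_itsa(series, 1), fit_itsa(series, 1)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.p_level == b.p_level and a.p_trend == b.p_trend

    def test_noiseless_pure_level_series_is_degenerate(self, rng):
        spec = ScenarioSpec(10, intervention_index=5, sigma=1e-14,
                            level_change_pct=50.0)
        series = simulate_series(spec, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_itsa(series, 1)
        assert fit.p_level < 1e-6
        assert fit.p_trend == 1.0  # zero coefficient, zero variance

    def test_csv_export_round_trip(self, rng, tmp_path):
        import pandas as pd

        fit = fit_itsa(random_series(rng), 1)
        path = tmp_path / "fit.csv"
        fit.to_csv(path)
        row = pd.read_csv(path).iloc[0]
        assert row["p_trend"] == pytest.approx(fit.p_trend)
        assert row["lag"] == 1


class TestBatchFit:
    def test_batch_agrees_with_per_series_fits(self, balanced_spec):
        from itsapower import simulate_outcomes
        from itsapower.dgp import SeriesData

        design, outcomes = simulate_outcomes(
            balanced_spec, 25, np.random.default_rng(9)
        )
        for use_t, small in [(False, False), (True, True)]:
            coefs, pvals = fit_itsa_batch(design, outcomes, 1,
                                          use_t=use_t, small_sample=small)
            for r in range(25):
                series = SeriesData(
                    time_index=np.arange(30),
                    intervention_indicator=design[:, 2].astype(int),
                    interaction=design[:, 3].astype(int),
                    outcome=outcomes[r],
                )
                fit = fit_itsa(series, 1, use_t=use_t, small_sample=small)
                np.testing.assert_allclose(coefs[r], fit.coefficients, rtol=1e-10)
                assert pvals[r, 2] == pytest.approx(fit.p_level, rel=1e-10)
                assert pvals[r, 3] == pytest.approx(fit.p_trend, rel=1e-10)
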