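"""Penalized-spline LMM fit: BLUP/ridge equivalence, REML, derivatives, bands."""

import warnings

import numpy as np
import pytest

from plateletfda.basis import SplineSpec, truncated_basis
from plateletfda.simulate import CurveFamilyParams, signal, simulate_curve
from plateletfda.splines import fit_penalized_spline, predict_curve

from conftest import dense_ridge_solution, random_spline_instance


class TestRidgeOracle:
    def test_fixed_lambda_matches_dense_normal_equations(self, rng):
        """BLUP solution == brute-force generalized ridge, small instances."""
        for _ in range(10):
            t, y, spec, lam = random_spline_instance(rng)
            fit = fit_penalized_spline((t, y), spec, smoothing=lam)
            oracle = dense_ridge_solution(t, y, spec, lam)
            scale = np.abs(oracle).max()
            np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8 * scale)

    def test_fitted_values_equal_design_times_coefficients(self, rng):
        t, y, spec, lam = random_spline_instance(rng)
        fit = fit_penalized_spline((t, y), spec, smoothing=lam)
        recon = fit.design_matrix(t) @ fit.coefficients
        np.testing.assert_allclose(recon, fit.fitted, atol=1e-8 * np.abs(y).max())

    def test_lambda_limits(self, rng):
        """lam -> 0: unpenalized LS on the full basis; lam -> inf: degree-p poly LS."""
        t = np.sort(rng.uniform(0, 7, 80))
        y = 30 * np.sin(t) + rng.normal(0, 1, 80)
        spec = SplineSpec(degree=3, knots=np.array([2.0, 4.0, 6.0]))
        P, T = truncated_basis(t, spec, 0, check_range=False)
        C = np.hstack([P, T])
        ls_full = np.linalg.lstsq(C, y, rcond=None)[0]
        fit_lo = fit_penalized_spline((t, y), spec, smoothing=1e-10)
        np.testing.assert_allclose(C @ fit_lo.coefficients, C @ ls_full, atol=1e-5)
        ls_poly = np.linalg.lstsq(P, y, rcond=None)[0]
        fit_hi = fit_penalized_spline((t, y), spec, smoothing=1e12)
        np.testing.assert_allclose(fit_hi.fitted, P @ ls_poly, atol=1e-5)


class TestREML:
    def test_reml_optimum_confirmed_by_dense_likelihood(self, rng):
        """The Woodbury-profiled optimum maximizes the dense-matrix REML.

        Independent oracle: the restricted likelihood evaluated with full
        n x n covariance matrices on a small problem.
        """
        t = np.sort(rng.uniform(0, 7, 60))
        y = 40 * np.sin(t / 2) + rng.normal(0, 1.5, 60)
        spec = SplineSpec(degree=3, knots=np.linspace(1, 6, 4))
        fit = fit_penalized_spline((t, y), spec)

        # dense REML on the raw basis with full n x n covariance matrices;
        # fit.lam is reported in the raw parameterization
        P, T = truncated_basis(t, spec, 0, check_range=False)

        def neg2_reml(lam):
            V = T @ T.T / lam + np.eye(len(t))
            Vi = np.linalg.inv(V)
            XtVX = P.T @ Vi @ P
            beta = np.linalg.solve(XtVX, P.T @ Vi @ y)
            r = y - P @ beta
            ypy = r @ Vi @ y
            df = len(t) - P.shape[1]
            _, logdetV = np.linalg.slogdet(V)
            _, logdetX = np.linalg.slogdet(XtVX)
            return df * np.log(ypy / df) + logdetV + logdetX

        at_opt = neg2_reml(fit.lam)
        for factor in (0.5, 0.8, 1.25, 2.0):
            assert at_opt <= neg2_reml(fit.lam * factor) + 1e-6

    def test_linear_signal_reproduced_exactly(self):
        t = np.linspace(0, 7, 60)
        y = 2.0 + 3.0 * t
        fit = fit_penalized_spline((t, y), knots=4)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-8)
        assert np.abs(fit.u).max() < 1e-6

    def test_noisy_sin_recovery_rmse_below_one(self):
        t = np.linspace(0, 7, 400)
        truth = 40 * np.sin(2 * np.pi * t / 7)
        rng = np.random.default_rng(5)
        fit = fit_penalized_spline((t, truth + rng.normal(0, 1, t.size)))
        rmse = np.sqrt(np.mean((predict_curve(fit, t).estimate - truth) ** 2))
        assert rmse < 1.0

    def test_variance_component_estimates_sane(self):
        params = CurveFamilyParams(family="saturating", amplitude=60, k=1.2, noise_sd=1.5)
        fit = fit_penalized_spline(simulate_curve(params, seed=3))
        assert np.sqrt(fit.sigma2_eps) == pytest.approx(1.5, rel=0.2)
        assert fit.sigma2_u > 0

    def test_polynomial_data_flags_polynomial_limit(self):
        t = np.linspace(0, 7, 100)
        y = 1.0 + 0.5 * t - 0.1 * t**2
        rng = np.random.default_rng(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_penalized_spline((t, y + rng.normal(0, 0.5, t.size)), knots=5)
        # a quadratic truth needs no truncated contribution
        assert fit.polynomial_limit or fit.sigma2_u < 1e-4

    def test_nonfinite_response_rejected(self):
        t = np.linspace(0, 7, 50)
        y = np.sin(t)
        y[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_penalized_spline((t, y), knots=3)

    def test_too_few_observations_rejected(self):
        spec = SplineSpec(degree=5, knots=np.linspace(1, 6, 10))
        t = np.linspace(0, 7, 10)
        with pytest.raises(ValueError, match="observations"):
            fit_penalized_spline((t, np.sin(t)), spec)

    def test_multi_condition_frame_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "dose": [0.2] * 30 + [0.4] * 30,
                "group": "agonist_only",
                "time_min": np.tile(np.linspace(0, 7, 30), 2),
                "aggregation_pct": np.random.default_rng(0).normal(size=60),
            }
        )
        with pytest.raises(ValueError, match="single condition"):
            fit_penalized_spline(df)


@pytest.fixture(scope="module")
def noisy_fit():
    params = CurveFamilyParams(
        family="rise_decay", amplitude=50, lam1=2.5, lam2=0.35, noise_sd=1.0
    )
    return fit_penalized_spline(simulate_curve(params, seed=9))


class TestPrediction:

    def test_deriv0_at_training_times_equals_fitted(self, noisy_fit):
        est = predict_curve(noisy_fit, noisy_fit.times, 0)
        np.testing.assert_allclose(est.estimate, noisy_fit.fitted, rtol=0, atol=1e-10)

    def test_constant_response_has_zero_derivative(self):
        t = np.linspace(0, 7, 80)
        fit = fit_penalized_spline((t, np.full(80, 42.0)), knots=5)
        est = predict_curve(fit, np.linspace(0.5, 6.5, 50), 1)
        assert np.abs(est.estimate).max() < 1e-8

    @pytest.mark.parametrize("order", [1, 2])
    def test_derivatives_match_finite_differences(self, noisy_fit, order):
        g = np.linspace(0.3, 6.7, 60)
        h = 1e-4
        if order == 1:
            fd = (
                predict_curve(noisy_fit, g + h).estimate
                - predict_curve(noisy_fit, g - h).estimate
            ) / (2 * h)
        else:
            fd = (
                predict_curve(noisy_fit, g + h).estimate
                - 2 * predict_curve(noisy_fit, g).estimate
                + predict_curve(noisy_fit, g - h).estimate
            ) / h**2
        est = predict_curve(noisy_fit, g, order).estimate
        scale = np.abs(est).max()
        assert np.abs(est - fd).max() < 1e-4 * max(scale, 1.0)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_curves_continuous_across_knots(self, noisy_fit, order):
        eps = 1e-7
        knots = noisy_fit.spec.knots
        left = predict_curve(noisy_fit, knots - eps, order).estimate
        right = predict_curve(noisy_fit, knots + eps, order).estimate
        scale = max(np.abs(left).max(), 1.0)
        assert np.abs(left - right).max() < 1e-5 * scale

    def test_band_geometry(self, noisy_fit):
        est = predict_curve(noisy_fit, np.linspace(0, 7, 50), 0, level=0.95)
        assert np.all(est.lower <= est.estimate)
        assert np.all(est.estimate <= est.upper)
        assert np.all((est.upper - est.lower)[est.se > 0] > 0)

    def test_higher_level_widens_bands(self, noisy_fit):
        g = np.linspace(0, 7, 20)
        w95 = predict_curve(noisy_fit, g, 0, level=0.95)
        w99 = predict_curve(noisy_fit, g, 0, level=0.99)
        assert np.all(w99.upper - w99.lower > w95.upper - w95.lower)

    def test_extrapolation_warns_not_errors(self, noisy_fit):
        with pytest.warns(UserWarning, match="outside the training range"):
            est = predict_curve(noisy_fit, np.array([-1.0, 8.0]), 0)
        assert np.all(np.isfinite(est.estimate))

    def test_invalid_deriv_order_rejected(self, noisy_fit):
        with pytest.raises(ValueError, match="deriv_order"):
            predict_curve(noisy_fit, np.array([1.0]), 3)
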