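import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from betaridge.beta_family import (
    beta_deviance_residuals,
    beta_logpdf,
    fit_beta_ml,
    fit_beta_ridge,
    inv_link_logit,
    link_logit,
    working_weights,
)
from betaridge.data_io import Dataset


class TestBetaLogpdf:
    def test_uniform_case_has_zero_log_density(self):
        for y in (0.1, 0.5, 0.9):
            assert beta_logpdf(y, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_shape_parameterized_density(self):
        """mu=0.3, phi=5 is the (a, b) = (1.5, 3.5) beta law."""
        got = beta_logpdf(0.3, 0.3, 5.0)
        want = stats.beta.logpdf(0.3, 1.5, 3.5)
        assert got == pytest.approx(want, abs=1e-12)

    def test_density_normalizes(self):
        val, _ = integrate.quad(
            lambda y: np.exp(beta_logpdf(y, 0.3, 5.0)), 0.0, 1.0
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_logpdf(0.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            beta_logpdf(0.5, 1.0, 2.0)
        with pytest.raises(ValueError):
            beta_logpdf(0.5, 0.5, -1.0)


class TestLogitLink:
    def test_symmetry_point(self):
        assert link_logit(0.5) == 0.0

    def test_known_value(self):
        assert inv_link_logit(3.0) == pytest.approx(0.95257, abs=5e-6)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1e-6, 1.0 - 1e-6))
    def test_round_trip(self, mu):
        assert inv_link_logit(link_logit(mu)) == pytest.approx(mu, abs=1e-12)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            link_logit(1.0)


class TestFitBetaMl:
    def test_matches_independent_ml_implementation(self, small_beta_dataset):
        """Cross-check against the beta-regression ML fit in statsmodels."""
        import statsmodels.api as sm
        from statsmodels.othermod.betareg import BetaModel

        fit = fit_beta_ml(small_beta_dataset)
        exog = sm.add_constant(small_beta_dataset.X.to_numpy())
        ref = BetaModel(small_beta_dataset.y, exog).fit(disp=0)
        np.testing.assert_allclose(
            fit.params.to_numpy(), ref.params[:-1], atol=1e-5
        )
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_loglik_at_fit_beats_truth(self, rng):
        n = 400
        x = rng.standard_normal(n)
        mu = 1.0 / (1.0 + np.exp(-(-1.0 + 0.5 * x)))
        y = rng.beta(mu * 15.0, (1.0 - mu) * 15.0)
        d = Dataset(pd.DataFrame({"x": x}), y, family_hint="unit_interval")
        fit = fit_beta_ml(d)
        ll_truth = float(np.sum(beta_logpdf(y, mu, 15.0)))
        assert fit.llf >= ll_truth

    def test_score_small_at_convergence(self, small_beta_dataset):
        fit = fit_beta_ml(small_beta_dataset)
        assert fit.converged
        assert fit.score_max < 1e-6

    def test_fitted_means_interior_and_kparams(self, small_beta_dataset):
        fit = fit_beta_ml(small_beta_dataset)
        assert fit.mu.min() > 0 and fit.mu.max() < 1
        assert fit.phi > 0
        assert fit.k_params == small_beta_dataset.p + 2

    def test_gaussian_family_rejected(self, wdbc_like):
        with pytest.raises(ValueError, match="unit_interval"):
            fit_beta_ml(wdbc_like)


class TestWorkingWeights:
    def test_exchangeable_case_equal_weights(self):
        w = working_weights(np.full(5, 0.5), 2.0)
        assert np.ptp(w) == 0.0 and w[0] > 0

    def test_positivity(self, rng):
        mu = rng.uniform(1e-3, 1 - 1e-3, 10000)
        for phi in (0.5, 5.0, 500.0):
            assert working_weights(mu, phi).min() > 0

    def test_information_matches_finite_difference_at_symmetric_point(self, rng):
        """At mu = 1/2 the observed and expected Hessians coincide exactly."""
        from betaridge.beta_family import _loglik

        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.beta(2.0, 2.0, size=n)
        beta = np.zeros(2)  # mu_i = 1/2 for every record
        phi = 4.0
        logy, log1y = np.log(y), np.log1p(-y)
        w = working_weights(np.full(n, 0.5), phi)
        XtWX = X.T @ (w[:, None] * X)
        eps = 1e-5
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                bpp = beta.copy(); bpp[i] += eps; bpp[j] += eps
                bpm = beta.copy(); bpm[i] += eps; bpm[j] -= eps
                bmp = beta.copy(); bmp[i] -= eps; bmp[j] += eps
                bmm = beta.copy(); bmm[i] -= eps; bmm[j] -= eps
                H[i, j] = (
                    _loglik(bpp, phi, X, y, logy, log1y)
                    - _loglik(bpm, phi, X, y, logy, log1y)
                    - _loglik(bmp, phi, X, y, logy, log1y)
                    + _loglik(bmm, phi, X, y, logy, log1y)
                ) / (4.0 * eps**2)
        np.testing.assert_allclose(XtWX, -H, rtol=1e-4)


class TestBetaRidge:
    def test_k_zero_recovers_ml(self, small_beta_dataset):
        fit = fit_beta_ridge(small_beta_dataset, k_policy=0.0)
        np.testing.assert_allclose(
            fit.params.to_numpy(), fit.ml_fit.params.to_numpy(), atol=1e-8
        )

    def test_huge_k_shrinks_to_zero(self, small_beta_dataset):
        fit = fit_beta_ridge(small_beta_dataset, k_policy=1e9)
        assert np.abs(fit.params.to_numpy()).max() < 1e-4

    def test_matches_bruteforce_lagrangian(self, small_beta_dataset):
        """Closed form equals the minimizer of the shrinkage Lagrangian."""
        ml = fit_beta_ml(small_beta_dataset)
        k = 0.2
        fit = fit_beta_ridge(small_beta_dataset, k_policy=k, ml_fit=ml)
        X, w = ml.X, ml.weights
        A = X.T @ (w[:, None] * X)
        bml = ml.params.to_numpy()

        def rho(b):
            d = b - bml
            return b @ b + (d @ (A @ d)) / k

        res = optimize.minimize(rho, bml, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 500})
        np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-6)

    def test_norm_nonincreasing_in_k(self, small_beta_dataset):
        ml = fit_beta_ml(small_beta_dataset)
        norms = [
            np.linalg.norm(
                fit_beta_ridge(small_beta_dataset, k_policy=k, ml_fit=ml)
                .params.to_numpy()
            )
            for k in (0.0, 0.1, 1.0, 10.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_wsse_decomposition_consistent(self, small_beta_dataset):
        fit = fit_beta_ridge(small_beta_dataset, k_policy=0.5)
        assert fit.theta_at_solution >= fit.theta_min


class TestDevianceResiduals:
    def test_deviance_identity_and_signs(self, small_beta_dataset):
        """Sum of squared residuals equals the deviance computed from an
        independently brute-force-maximized saturated likelihood."""
        fit = fit_beta_ml(small_beta_dataset)
        r = beta_deviance_residuals(fit)
        ll_sat = np.array([
            -optimize.minimize_scalar(
                lambda m, yi=yi: -beta_logpdf(yi, m, fit.phi),
                bounds=(1e-9, 1 - 1e-9), method="bounded",
                options={"xatol": 1e-12},
            ).fun
            for yi in fit.y
        ])
        dev = 2.0 * np.sum(ll_sat - beta_logpdf(fit.y, fit.mu, fit.phi))
        assert np.sum(r**2) == pytest.approx(dev, abs=1e-6)
        np.testing.assert_array_equal(np.sign(r), np.sign(fit.y - fit.mu))

    def test_roughly_symmetric_on_emulated_table(self, wdbc_like):
        from betaridge.data_io import prepare_beta_response

        d = Dataset(
            wdbc_like.X, prepare_beta_response(wdbc_like.y, 100.0),
            family_hint="unit_interval",
        )
        fit = fit_beta_ml(d)
        r = beta_deviance_residuals(fit)
        assert abs(np.mean(r)) < 0.1
        # the emulated table is mildly skewed on the unit-interval scale
        assert abs(np.median(r)) < 0.5
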