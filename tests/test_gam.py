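import numpy as np
import pandas as pd
import pytest

from betaridge.beta_family import fit_beta_ml
from betaridge.data_io import Dataset
from betaridge.gam import (
    build_crs_basis,
    effective_dof,
    fit_gam,
    gam_deviance_residuals,
    penalized_loglik,
    predict_gam,
)
from betaridge.linear_ridge import fit_ols


@pytest.fixture()
def xgrid(rng):
    return np.sort(rng.uniform(0.0, 1.0, 200))


class TestCrsBasis:
    def test_linear_function_has_zero_penalty(self, xgrid):
        _, _, basis = build_crs_basis(xgrid, 8, constrain=False)
        beta = 2.0 * basis.knots + 1.0  # knot values of f(x) = 2x + 1
        assert beta @ basis.penalty_raw @ beta == pytest.approx(0.0, abs=1e-10)

    def test_penalty_null_space_dimension_is_two(self, xgrid):
        _, _, basis = build_crs_basis(xgrid, 8, constrain=False)
        ev = np.linalg.eigvalsh(basis.penalty_raw)
        assert np.sum(ev < ev.max() * 1e-10) == 2
        assert np.all(ev[2:] > 0)

    def test_interpolation_property(self, xgrid, rng):
        """The spline in value parameterization passes through its knot values."""
        _, _, basis = build_crs_basis(xgrid, 8, constrain=False)
        vals = rng.standard_normal(basis.k)
        at_knots = basis._design_raw(basis.knots, warn_extrapolation=False) @ vals
        np.testing.assert_allclose(at_knots, vals, atol=1e-8)

    def test_constraint_reduces_columns_and_centers(self, xgrid):
        B, S, basis = build_crs_basis(xgrid, 8)
        assert B.shape[1] == 7
        assert abs(B.sum()) < 1e-8  # sum-to-zero over the data

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_crs_basis(np.array([0.0, 1.0, 2.0] * 10), 6)

    def test_extrapolation_is_linear_and_warns(self, xgrid):
        _, _, basis = build_crs_basis(xgrid, 6, constrain=False)
        lo = basis.knots[0]
        with pytest.warns(UserWarning, match="outside"):
            rows = basis._design_raw(np.array([lo - 0.3, lo - 0.2, lo - 0.1]))
        # second differences vanish for a linear extension
        second = rows[0] - 2 * rows[1] + rows[2]
        np.testing.assert_allclose(second, 0.0, atol=1e-10)


class TestPenalizedLoglik:
    def test_arithmetic_cases(self):
        S = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert penalized_loglik(-10.0, [1.0, 1.0], [0.0], [S]) == -10.0
        # beta'Sbeta = 3 with lambda = 2 -> -10 - 3 = -13
        assert penalized_loglik(-10.0, [1.0, 1.0], [2.0], [S]) == -13.0

    def test_null_space_vector_unpenalized(self):
        S = np.array([[1.0, -1.0], [-1.0, 1.0]])  # null space: constants
        assert penalized_loglik(-5.0, [3.0, 3.0], [100.0], [S]) == -5.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            penalized_loglik(0.0, [1.0], [-1.0], [np.eye(1)])


class TestGaussianGam:
    def test_no_smooth_reduces_to_ols(self, rng):
        X = rng.standard_normal((40, 2))
        y = X @ [1.0, -0.5] + rng.standard_normal(40)
        d = Dataset(pd.DataFrame(X, columns=["a", "b"]), y)
        g = fit_gam(d, [{"var": "a"}, {"var": "b"}], family="gaussian")
        o = fit_ols(d)
        np.testing.assert_allclose(
            g.params.to_numpy(), o.params.to_numpy(), atol=1e-8
        )
        assert g.edf_total == pytest.approx(3.0)
        assert g.llf == pytest.approx(o.llf, abs=1e-8)

    def test_fixed_lambda_matches_closed_form(self, rng):
        from betaridge.gam import _assemble, _normalize_terms, _penalty_total

        x = rng.uniform(0, 1, 150)
        y = np.sin(2 * np.pi * x) + 0.1 * rng.standard_normal(150)
        d = Dataset(pd.DataFrame({"x": x}), y)
        lam = 2.5
        g = fit_gam(d, [{"var": "x", "smooth": True, "k": 10}], lambdas=[lam])
        terms = _normalize_terms(d, [{"var": "x", "smooth": True, "k": 10}], 10)
        X, _, _, sm = _assemble(d, terms)
        S = _penalty_total(X.shape[1], sm, [lam])
        closed = np.linalg.solve(X.T @ X + S, X.T @ y)
        np.testing.assert_allclose(g.params.to_numpy(), closed, atol=1e-8)

    def test_function_recovery(self):
        """REML smooth recovers a sine signal in nearly every seed."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 1, 500)
            truth = np.sin(2 * np.pi * x)
            y = truth + 0.1 * r.standard_normal(500)
            d = Dataset(pd.DataFrame({"x": x}), y)
            g = fit_gam(d, [{"var": "x", "smooth": True, "k": 10}])
            hits += np.corrcoef(g.fittedvalues, truth)[0, 1] > 0.98
        assert hits >= 9

    def test_penalized_loglik_below_unpenalized(self, rng):
        x = rng.uniform(0, 1, 200)
        y = np.sin(2 * np.pi * x) + 0.2 * rng.standard_normal(200)
        d = Dataset(pd.DataFrame({"x": x}), y)
        g = fit_gam(d, [{"var": "x", "smooth": True, "k": 10}])
        assert g.llf_penalized <= g.llf + 1e-12


class TestEffectiveDof:
    @pytest.fixture()
    def smooth_data(self, rng):
        x = rng.uniform(0, 1, 200)
        y = np.sin(2 * np.pi * x) + 0.2 * rng.standard_normal(200)
        return Dataset(pd.DataFrame({"x": x}), y)

    def test_lambda_zero_gives_coefficient_count(self, smooth_data):
        g = fit_gam(smooth_data, [{"var": "x", "smooth": True, "k": 10}],
                    lambdas=[0.0])
        total, per = effective_dof(g)
        assert total == pytest.approx(10.0, abs=1e-8)  # 1 + (10 - 1) columns

    def test_infinite_smoothing_leaves_linear_trend(self, smooth_data):
        g = fit_gam(smooth_data, [{"var": "x", "smooth": True, "k": 10}],
                    lambdas=[1e12])
        _, per = effective_dof(g)
        assert per["x"] == pytest.approx(1.0, abs=0.05)

    def test_edf_monotone_in_lambda(self, smooth_data):
        edfs = [
            effective_dof(
                fit_gam(smooth_data, [{"var": "x", "smooth": True, "k": 10}],
                        lambdas=[lam])
            )[0]
            for lam in (0.0, 0.1, 10.0, 1000.0)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(edfs, edfs[1:]))


class TestBetaGam:
    def test_all_parametric_reproduces_beta_ml(self, small_beta_dataset):
        g = fit_gam(small_beta_dataset,
                    [{"var": c} for c in small_beta_dataset.column_names],
                    family="beta")
        b = fit_beta_ml(small_beta_dataset)
        np.testing.assert_allclose(
            g.params.to_numpy(), b.params.to_numpy(), atol=1e-6
        )
        assert g.scale == pytest.approx(b.phi, rel=1e-6)

    def test_smooth_fit_recovers_nonlinear_mean(self, rng):
        x = rng.uniform(0, 1, 400)
        mu = 1.0 / (1.0 + np.exp(-(0.5 + np.sin(2 * np.pi * x))))
        y = np.clip(rng.beta(mu * 15, (1 - mu) * 15), 1e-9, 1 - 1e-9)
        d = Dataset(pd.DataFrame({"x": x}), y, family_hint="unit_interval")
        g = fit_gam(d, [{"var": "x", "smooth": True, "k": 10}], family="beta")
        assert np.corrcoef(g.fittedvalues, mu)[0, 1] > 0.97
        assert g.fittedvalues.min() > 0 and g.fittedvalues.max() < 1

    def test_gaussian_response_rejected_for_beta_family(self, wdbc_like):
        with pytest.raises(ValueError, match="unit_interval"):
            fit_gam(wdbc_like, None, family="beta")


class TestPredict:
    def test_training_predictions_match_fitted(self, rng):
        x = rng.uniform(0, 1, 200)
        z = rng.standard_normal(200)
        y = np.sin(2 * np.pi * x) + 0.5 * z + 0.1 * rng.standard_normal(200)
        d = Dataset(pd.DataFrame({"x": x, "z": z}), y)
        g = fit_gam(d, [{"var": "x", "smooth": True, "k": 8}, {"var": "z"}])
        pred = predict_gam(g, d.X)
        np.testing.assert_allclose(pred, g.fittedvalues, atol=1e-10)

    def test_unknown_column_rejected(self, rng):
        x = rng.uniform(0, 1, 100)
        d = Dataset(pd.DataFrame({"x": x}), x + 0.1 * rng.standard_normal(100))
        g = fit_gam(d, [{"var": "x", "smooth": True, "k": 6}])
        with pytest.raises(KeyError, match="x"):
            predict_gam(g, pd.DataFrame({"wrong": [0.5]}))

    def test_gaussian_deviance_residuals_are_response_residuals(self, rng):
        x = rng.uniform(0, 1, 100)
        y = x + 0.1 * rng.standard_normal(100)
        d = Dataset(pd.DataFrame({"x": x}), y)
        g = fit_gam(d, [{"var": "x"}])
        np.testing.assert_allclose(
            gam_deviance_residuals(g), y - g.fittedvalues, atol=1e-12
        )
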