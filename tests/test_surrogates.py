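"""Surrogate families: PCE, Kriging, PC-Kriging, and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from math import comb

from mguq.doe import ParameterSpace, sample_one_shot
from mguq.surrogates import (
    KrigingModel,
    PCEModel,
    build_index_set,
    fit_kriging,
    fit_pce,
    fit_pck,
    matern52,
)
from mguq.surrogates.pce import _legendre_orthonormal


class TestIndexSet:
    def test_univariate_full_set(self):
        alphas = build_index_set(1, 3, 1.0)
        assert sorted(a[0] for a in alphas) == [0, 1, 2, 3]

    @pytest.mark.parametrize("n, p", [(2, 3), (3, 4), (8, 2)])
    def test_total_degree_count_formula(self, n, p):
        assert build_index_set(n, p, 1.0).shape[0] == comb(p + n, n)

    def test_hyperbolic_subset_by_brute_force(self):
        full = {tuple(a) for a in build_index_set(2, 3, 1.0)}
        hyp = {tuple(a) for a in build_index_set(2, 3, 0.5)}
        assert hyp < full
        for a in full:
            expected = (sum(x**0.5 for x in a)) ** 2 <= 3 + 1e-12
            assert (a in hyp) == expected

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            build_index_set(2, 3, 1.5)

    def test_basis_orthonormal_under_uniform_measure(self):
        """Gauss-Legendre quadrature check of the normalised basis."""
        nodes, weights = np.polynomial.legendre.leggauss(40)
        V = _legendre_orthonormal(nodes, 8)
        gram = (V * weights[:, None]).T @ V / 2.0  # uniform density 1/2
        assert np.abs(gram - np.eye(9)).max() < 1e-8


class TestPce:
    def test_constant_response(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 15, "lhs", seed=0).points
        Y = np.full(15, 3.7)
        with pytest.warns(RuntimeWarning, match="constant"):
            model = fit_pce(X, Y, degree_range=range(1, 3))
        assert model.coefficients[0] == pytest.approx(3.7)
        assert np.abs(model.coefficients[1:]).max() < 1e-10
        assert model.loo_error_ == 0.0

    def test_exact_polynomial_reproduction(self, box_space_2d, rng):
        X = sample_one_shot(box_space_2d, 40, "lhs", seed=1).points

        def f(x):
            return 1 + 2 * x[:, 0] - 0.5 * x[:, 1] ** 2 + 0.3 * x[:, 0] * x[:, 1]

        model = fit_pce(X, f(X), degree_range=range(1, 5), q=1.0)
        Xt = sample_one_shot(box_space_2d, 25, "mc", seed=2).points
        assert np.abs(model.predict(Xt) - f(Xt)).max() < 1e-10

    def test_normal_equations_oracle(self):
        """LS coefficients match an independent normal-equations solve."""
        from mguq.cases import model1_mdd28, model1_space

        space = model1_space()
        X = sample_one_shot(space, 25, "lhs", seed=4).points
        Y = np.array([model1_mdd28(x) for x in X])
        model = fit_pce(X, Y, degree_range=[3], q=1.0, space=space)
        psi = model.basis_eval(X)
        coef_oracle = np.linalg.solve(psi.T @ psi, psi.T @ Y)
        Xt = sample_one_shot(space, 10, "mc", seed=5).points
        pred_oracle = model.basis_eval(Xt) @ coef_oracle
        assert np.abs(model.predict(Xt) - pred_oracle).max() < 1e-8 * np.ptp(Y)

    def test_degree_selected_by_loo(self, rng):
        sp = ParameterSpace([("x", -1.0, 1.0)])
        X = sample_one_shot(sp, 50, "lhs", seed=6).points
        Y = np.sin(3 * X[:, 0])
        model = fit_pce(X, Y, degree_range=range(1, 10), q=1.0)
        assert model.loo_error_ == min(model.degree_history.values())
        assert model.degree >= 5  # sin needs a few terms

    def test_infeasible_degrees_raise(self):
        X = np.random.default_rng(0).random((3, 4))
        with pytest.raises(ValueError, match="feasible"):
            fit_pce(X, np.ones(3), degree_range=[4])

    def test_serialization_roundtrip(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 20, "lhs", seed=7).points
        Y = X[:, 0] ** 2 + X[:, 1]
        model = fit_pce(X, Y, degree_range=range(1, 4))
        clone = PCEModel.from_dict(model.to_dict())
        Xt = sample_one_shot(box_space_2d, 9, "mc", seed=8).points
        assert np.allclose(clone.predict(Xt), model.predict(Xt))


class TestMatern:
    def test_limits(self):
        assert matern52(0.0, 1.3) == 1.0
        assert matern52(1e6, 0.5) < 1e-12

    def test_value_at_r_equal_theta(self):
        expected = (1 + np.sqrt(5) + 5 / 3) * np.exp(-np.sqrt(5))
        assert matern52(2.0, 2.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.52399, abs=5e-6)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_valid_correlation_range(self, r, theta):
        v = matern52(r, theta)
        assert 0.0 <= v <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            matern52(-1.0, 1.0)
        with pytest.raises(ValueError):
            matern52(1.0, 0.0)


class TestKriging:
    def test_linear_trend_predicts_held_out(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 20, "lhs", seed=0).points
        Y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5
        model = fit_kriging(X, Y, bounds=box_space_2d.bounds, seed=0)
        Xt = sample_one_shot(box_space_2d, 10, "mc", seed=1).points
        Yt = 3.0 * Xt[:, 0] - 2.0 * Xt[:, 1] + 0.5
        assert np.abs(model.predict(Xt) - Yt).max() < 1e-3 * np.ptp(Y)

    def test_interpolation_contract(self, box_space_2d, rng):
        X = sample_one_shot(box_space_2d, 30, "lhs", seed=2).points
        Y = np.sin(X[:, 0]) + 0.3 * X[:, 1] ** 2
        model = fit_kriging(X, Y, bounds=box_space_2d.bounds, seed=0)
        assert np.abs(model.predict(X) - Y).max() < 1e-6 * np.ptp(Y)

    def test_duplicated_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="d"):
            fit_kriging(X, np.ones(4))

    def test_blup_oracle_fixed_hyperparameters(self):
        """Predictive mean equals the dense-linear-algebra BLUP formula."""
        rng = np.random.default_rng(3)
        X = rng.random((6, 2))
        Y = np.cos(4 * X[:, 0]) + X[:, 1]
        theta = np.array([0.4, 0.9])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        model = fit_kriging(X, Y, theta0=theta, optimize=False, bounds=b)
        Xt = rng.random((5, 2))
        # independent dense computation
        from scipy.spatial.distance import cdist

        R = matern52(cdist(X / theta, X / theta)) + model.nugget * np.eye(6)
        F = np.ones((6, 1))
        Rinv = np.linalg.inv(R)
        beta = np.linalg.solve(F.T @ Rinv @ F, F.T @ Rinv @ Y)
        r = matern52(cdist(Xt / theta, X / theta))
        mu = (F[:5, :1] * 0 + 1) @ beta + r @ Rinv @ (Y - F @ beta)
        assert np.abs(model.predict(Xt) - mu.ravel()).max() < 1e-10

    def test_predictive_variance_zero_at_training_points(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 15, "lhs", seed=4).points
        Y = X[:, 0] * X[:, 1]
        model = fit_kriging(X, Y, bounds=box_space_2d.bounds, seed=0)
        _, var = model.predict(X, return_var=True)
        assert var.max() < 1e-6 * model.sigma2 + 1e-12

    def test_agrees_with_sklearn_gp(self):
        """Independent cross-check: fixed-kernel sklearn GP on residuals."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        rng = np.random.default_rng(5)
        X = rng.random((12, 2))
        Y = np.sin(3 * X[:, 0]) * X[:, 1]
        theta = np.array([0.5, 0.7])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        model = fit_kriging(X, Y, theta0=theta, optimize=False, bounds=b, nugget=1e-10)
        beta = float(model.beta[0])
        gp = GaussianProcessRegressor(
            kernel=Matern(length_scale=theta, nu=2.5),
            alpha=1e-10,
            optimizer=None,
        )
        gp.fit(X, Y - beta)
        Xt = rng.random((7, 2))
        assert np.abs(model.predict(Xt) - (gp.predict(Xt) + beta)).max() < 1e-8

    def test_serialization_roundtrip(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 12, "lhs", seed=5).points
        Y = X[:, 0] + np.sin(X[:, 1])
        model = fit_kriging(X, Y, bounds=box_space_2d.bounds, seed=0)
        clone = KrigingModel.from_dict(model.to_dict())
        Xt = sample_one_shot(box_space_2d, 6, "mc", seed=6).points
        assert np.allclose(clone.predict(Xt), model.predict(Xt), atol=1e-12)


class TestPck:
    def test_polynomial_response_degenerates_to_pce(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 30, "lhs", seed=0).points
        Y = 2.0 + X[:, 0] ** 2 - X[:, 1]
        model = fit_pck(X, Y, degree_range=range(1, 4), q=1.0, seed=0)
        assert model.kriging_residual.sigma2 < 1e-10 * np.var(Y)
        Xt = sample_one_shot(box_space_2d, 10, "mc", seed=1).points
        assert np.abs(model.predict(Xt) - (2.0 + Xt[:, 0] ** 2 - Xt[:, 1])).max() < 1e-6

    def test_constant_trend_equals_ordinary_kriging(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 15, "lhs", seed=2).points
        Y = np.sin(X[:, 0]) * X[:, 1]
        pce0 = fit_pce(X, Y, degree_range=[0], q=1.0)
        krig_pck = fit_kriging(X, Y, trend=pce0, bounds=box_space_2d.bounds, seed=0)
        krig_ord = fit_kriging(X, Y, trend="constant", bounds=box_space_2d.bounds, seed=0)
        Xt = sample_one_shot(box_space_2d, 8, "mc", seed=3).points
        assert np.allclose(krig_pck.predict(Xt), krig_ord.predict(Xt), rtol=1e-6)

    def test_interpolates_training_data(self, box_space_2d):
        X = sample_one_shot(box_space_2d, 25, "lhs", seed=4).points
        Y = np.exp(-X[:, 0]) + 0.1 * X[:, 1] ** 3
        model = fit_pck(X, Y, seed=0)
        assert np.abs(model.predict(X) - Y).max() < 1e-6 * np.ptp(Y)

    def test_not_worse_than_pce_on_model1_data(self):
        """Combining a GP residual with the PCE trend should not lose to
        the PCE alone on the same training set."""
        from mguq.cases import model1_mdd28, model1_space

        space = model1_space()
        X = sample_one_shot(space, 25, "lhs", seed=9).points
        Y = np.array([model1_mdd28(x) for x in X])
        # same candidate degrees for both, so the trend basis matches
        degrees = range(1, 6)
        pce = fit_pce(X, Y, degree_range=degrees, space=space)
        pck = fit_pck(X, Y, degree_range=degrees, space=space, seed=0)
        assert pck.loo_error_ <= pce.loo_error_ + 1e-6
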