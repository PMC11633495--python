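"""Sobol indices (analytic + MC), propagation, and calibration."""

import numpy as np
import pytest

from mguq.doe import ParameterSpace, sample_one_shot
from mguq.surrogates import fit_pce
from mguq.surrogates.pce import PCEModel, build_index_set
from mguq.uq_analysis import calibrate, propagate, sobol_from_pce, sobol_mc


def _pce_from_coefficients(coef_map, n_dims, bounds=None):
    """Construct a PCE directly from {multi-index: coefficient}."""
    p = max(sum(a) for a in coef_map)
    index_set = build_index_set(n_dims, p, 1.0)
    coefs = np.zeros(index_set.shape[0])
    for t, alpha in enumerate(index_set):
        coefs[t] = coef_map.get(tuple(alpha), 0.0)
    if bounds is None:
        bounds = np.tile([-1.0, 1.0], (n_dims, 1))
    return PCEModel(
        index_set=index_set, coefficients=coefs, degree=p, q=1.0, bounds=bounds
    )


class TestSobolAnalytic:
    def test_additive_model_indices_sum_to_one(self):
        model = _pce_from_coefficients({(1, 0): 2.0, (0, 1): 1.0, (2, 0): 0.5}, 2)
        s = sobol_from_pce(model)
        assert np.allclose(s.first_order, s.total)
        assert s.first_order.sum() == pytest.approx(1.0)

    def test_single_input_gets_everything(self):
        model = _pce_from_coefficients({(3,): 1.2, (1,): 0.4}, 1)
        s = sobol_from_pce(model)
        assert s.first_order[0] == pytest.approx(1.0)
        assert s.total[0] == pytest.approx(1.0)

    def test_interaction_coefficients_analytic(self):
        a, b, c = 1.5, -0.7, 0.9
        model = _pce_from_coefficients({(1, 0): a, (0, 1): b, (1, 1): c}, 2)
        s = sobol_from_pce(model)
        D = a**2 + b**2 + c**2
        assert s.first_order[0] == pytest.approx(a**2 / D)
        assert s.total[0] == pytest.approx((a**2 + c**2) / D)
        assert s.first_order[1] == pytest.approx(b**2 / D)

    def test_constant_model_rejected(self):
        model = _pce_from_coefficients({(0, 0): 4.0}, 2)
        with pytest.raises(ValueError):
            sobol_from_pce(model)

    def test_invariant_to_physical_rescaling(self):
        """Indices are properties of the function on the box, not its units."""
        sp_a = ParameterSpace([("x", 0.0, 1.0), ("y", 0.0, 1.0)])
        sp_b = ParameterSpace([("x", -3e4, 7e4), ("y", 1e-9, 5e-9)])

        def f(U):
            return np.sin(3 * U[:, 0]) + 0.5 * U[:, 1] + U[:, 0] * U[:, 1]

        indices = []
        for sp in (sp_a, sp_b):
            X = sample_one_shot(sp, 60, "lhs", seed=1).points
            U = sp.to_unit(X)
            model = fit_pce(X, f(U), degree_range=range(1, 6), q=1.0, bounds=sp.bounds)
            indices.append(sobol_from_pce(model))
        assert np.allclose(indices[0].first_order, indices[1].first_order, atol=1e-6)
        assert np.allclose(indices[0].total, indices[1].total, atol=1e-6)


class TestSobolMc:
    def test_ignored_parameter_is_insensitive(self, unit_space_2d):
        def f(X):
            return np.atleast_2d(X)[:, 0] ** 2

        class M:
            def predict(self, X):
                return f(X)

        s = sobol_mc(M(), unit_space_2d, n=2048, seed=0)
        assert abs(s.first_order[1]) <= 3 * s.se_first[1] + 1e-3
        assert abs(s.total[1]) <= 3 * s.se_total[1] + 1e-3

    def test_linear_additive_closed_form(self):
        sp = ParameterSpace([("x", 0.0, 1.0), ("y", 0.0, 2.0)])
        c1, c2 = 2.0, 1.0  # Var contributions: c1^2/12, c2^2*4/12

        class M:
            def predict(self, X):
                X = np.atleast_2d(X)
                return c1 * X[:, 0] + c2 * X[:, 1]

        s = sobol_mc(M(), sp, n=4096, seed=1)
        v1 = c1**2 / 12
        v2 = c2**2 * 4 / 12
        expected = np.array([v1, v2]) / (v1 + v2)
        for est, se, ref in zip(s.first_order, s.se_first, expected):
            assert abs(est - ref) <= 3 * se + 1e-3
        for est, se, ref in zip(s.total, s.se_total, expected):
            assert abs(est - ref) <= 3 * se + 1e-3

    def test_mc_agrees_with_analytic_pce_path(self):
        model = _pce_from_coefficients(
            {(1, 0): 1.0, (0, 1): 0.6, (1, 1): 0.3, (2, 0): 0.2}, 2
        )
        sp = ParameterSpace([("x", -1.0, 1.0), ("y", -1.0, 1.0)])
        exact = sobol_from_pce(model)
        mc = sobol_mc(model, sp, n=4096, seed=2)
        for est, se, ref in zip(mc.first_order, mc.se_first, exact.first_order):
            assert abs(est - ref) <= 3 * se + 1e-3
        for est, se, ref in zip(mc.total, mc.se_total, exact.total):
            assert abs(est - ref) <= 3 * se + 1e-3

    def test_small_n_rejected(self, unit_space_2d):
        with pytest.raises(ValueError):
            sobol_mc(lambda x: 0.0, unit_space_2d, n=32)


class TestPropagate:
    def test_constant_model_zero_variance(self, unit_space_2d):
        class M:
            def predict(self, X):
                return np.full(np.atleast_2d(X).shape[0], 7.0)

        res = propagate(M(), unit_space_2d, n=200, seed=0)
        assert res.variance == 0.0
        assert res.mean == 7.0

    def test_identity_model_uniform_moments(self):
        a, b = 2.0, 6.0
        sp = ParameterSpace([("x", a, b)])

        class M:
            def predict(self, X):
                return np.atleast_2d(X)[:, 0]

        res = propagate(M(), sp, n=4000, seed=1)
        se_mean = np.sqrt((b - a) ** 2 / 12 / 4000)
        assert abs(res.mean - (a + b) / 2) <= 3 * se_mean
        assert res.variance == pytest.approx((b - a) ** 2 / 12, rel=0.1)
        assert res.quantiles[0.5] == pytest.approx(4.0, abs=0.1)
        # quantiles are monotone
        qs = [res.quantiles[k] for k in sorted(res.quantiles)]
        assert np.all(np.diff(qs) >= 0)

    def test_failure_rate_guard(self, unit_space_2d):
        class Flaky:
            def predict(self, X):
                X = np.atleast_2d(X)
                out = X[:, 0].copy()
                out[X[:, 0] > 0.5] = np.nan
                return out

        with pytest.raises(RuntimeError, match="failure rate"):
            propagate(Flaky(), unit_space_2d, n=200, seed=2)


class TestCalibrate:
    def test_noiseless_self_consistency(self):
        """Observations generated by the surrogate itself are recovered."""
        sp = ParameterSpace([("a", 0.0, 1.0), ("b", 0.0, 1.0)])
        X = sample_one_shot(sp, 40, "lhs", seed=0).points
        times = np.array([1.0, 2.0, 3.0])

        def truth(x, t):
            return (1 + x[..., 0:1]) * t[None, :] + x[..., 1:2] ** 2

        from mguq.surrogates import fit_time_grid, fit_kriging

        Y = truth(X, times)
        sur = fit_time_grid(
            lambda A, B: fit_kriging(A, B, bounds=sp.bounds, seed=0), X, Y, times
        )
        theta_star = np.array([0.321, 0.654])
        from mguq.degradation_models import TimeSeriesOutput

        obs = TimeSeriesOutput(times=times, values=truth(theta_star[None], times)[0])
        result = calibrate(sur, obs, sp, n_screen=400, seed=1)
        assert abs(result.params["a"] - theta_star[0]) < 0.01
        assert abs(result.params["b"] - theta_star[1]) < 0.01
        assert result.objective <= result.trace[0]["objective"] + 1e-15

    def test_optimum_inside_bounds(self):
        sp = ParameterSpace([("a", -1.0, 1.0)])

        class M:
            def predict_at(self, X, t):
                X = np.atleast_2d(X)
                return np.column_stack([X[:, 0] * tt for tt in t])

        from mguq.degradation_models import TimeSeriesOutput

        obs = TimeSeriesOutput(times=np.array([1.0, 2.0]), values=np.array([5.0, 10.0]))
        result = calibrate(M(), obs, sp, n_screen=100, seed=0)
        assert -1.0 <= result.params["a"] <= 1.0  # target slope 5 is outside
        assert result.params["a"] == pytest.approx(1.0, abs=1e-3)
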