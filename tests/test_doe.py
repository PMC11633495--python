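"""Design of experiments: samplers, CMM selection, adaptive loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mguq.doe import (
    ParameterSpace,
    adaptive_sample,
    cmm_select,
    min_one_shot_size,
    sample_one_shot,
)
from mguq.surrogates import fit_kriging


class TestParameterSpace:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace([("a", 0, 1), ("a", 0, 2)])

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace([("a", 1.0, 1.0)])

    def test_log_scale_needs_consistent_sign(self):
        with pytest.raises(ValueError):
            ParameterSpace([("a", -1.0, 1.0)], scales=["log"])

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_unit_roundtrip(self, u1, u2):
        sp = ParameterSpace(
            [("k", -1e-4, -1e-9), ("t", 0.0, 3.0)], scales=["log", "linear"]
        )
        u = np.array([[u1, u2]])
        x = sp.from_unit(u)
        assert np.allclose(sp.to_unit(x), u, atol=1e-12)
        assert sp.contains(x).all()

    def test_log_scale_samples_every_decade(self):
        sp = ParameterSpace([("D", 1e-12, 1e-4)], scales=["log"])
        pts = sample_one_shot(sp, 256, "lhs", seed=0).points.ravel()
        decades = np.floor(np.log10(pts))
        assert len(np.unique(decades)) == 8  # all of 1e-12..1e-4 visited


class TestMinOneShotSize:
    @pytest.mark.parametrize("n, expected", [(2, 22), (8, 82), (1, 12)])
    def test_rule(self, n, expected):
        assert min_one_shot_size(n) == expected

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            min_one_shot_size(0)


class TestOneShotSamplers:
    @pytest.mark.parametrize("method", ["mc", "lhs", "sobol", "halton"])
    def test_in_bounds_and_deterministic(self, method, box_space_2d):
        a = sample_one_shot(box_space_2d, 33, method, seed=42)
        b = sample_one_shot(box_space_2d, 33, method, seed=42)
        assert np.array_equal(a.points, b.points)
        assert box_space_2d.contains(a.points).all()

    def test_unknown_method(self, box_space_2d):
        with pytest.raises(ValueError):
            sample_one_shot(box_space_2d, 4, "urqmd")

    def test_lhs_1d_one_point_per_quartile(self):
        sp = ParameterSpace([("x", 2.0, 10.0)])
        pts = sample_one_shot(sp, 4, "lhs", seed=1).points.ravel()
        strata = np.floor((pts - 2.0) / 8.0 * 4).astype(int)
        assert sorted(strata) == [0, 1, 2, 3]

    def test_lhs_marginal_stratification_brute_force(self, unit_space_2d):
        n = 1000
        pts = sample_one_shot(unit_space_2d, n, "lhs", seed=3).points
        for j in range(2):
            counts = np.histogram(pts[:, j], bins=n, range=(0, 1))[0]
            assert np.all(counts == 1)


class TestCmmSelect:
    def test_pool_equal_to_design_ties_to_first(self, unit_space_2d, rng):
        design = rng.random((5, 2))
        assert cmm_select(design, design, unit_space_2d) == 0

    def test_1d_maximin_symmetry(self):
        sp = ParameterSpace([("x", 0.0, 1.0)])
        design = np.array([[0.0], [1.0]])
        pool = np.linspace(0, 1, 101)[:, None]
        chosen = pool[cmm_select(pool, design, sp)][0]
        assert chosen == pytest.approx(0.5)

    def test_matches_exhaustive_oracle(self, unit_space_2d, rng):
        design = rng.random((12, 2))
        pool = rng.random((200, 2))
        idx = cmm_select(pool, design, unit_space_2d)
        d = np.sqrt(((pool[:, None, :] - design[None]) ** 2).sum(axis=2)).min(axis=1)
        assert idx == int(np.argmax(d))

    def test_empty_pool(self, unit_space_2d):
        with pytest.raises(ValueError):
            cmm_select(np.empty((0, 2)), np.zeros((1, 2)), unit_space_2d)

    def test_variance_constraint_restricts_candidates(self, unit_space_2d):
        class FakeSurrogate:
            def predict(self, X, return_var=False):
                X = np.atleast_2d(X)
                var = X[:, 0]  # variance grows with x1
                return np.zeros(len(X)), var

        design = np.array([[0.5, 0.5]])
        pool = np.column_stack([np.linspace(0, 1, 100), np.full(100, 0.5)])
        idx = cmm_select(pool, design, unit_space_2d, surrogate=FakeSurrogate())
        assert pool[idx, 0] >= np.quantile(pool[:, 0], 0.75)


class TestAdaptiveSample:
    @staticmethod
    def _linear(x):
        return 2.0 * x[0] - 3.0 * x[1] + 1.0

    def test_linear_model_terminates_at_initial_design(self, unit_space_2d):
        def linear_trend(X):
            X = np.atleast_2d(X)
            return np.column_stack([np.ones(len(X)), X])

        state, model = adaptive_sample(
            self._linear,
            unit_space_2d,
            lambda X, Y: fit_kriging(
                X, Y, trend=linear_trend, bounds=unit_space_2d.bounds, seed=0
            ),
            theta=1e-4,
            budget=40,
            seed=11,
        )
        assert state.stop_reason == "eps_loo < theta"
        assert state.n == state.n_initial == 10
        assert state.eps_loo_history[-1] < 1e-4

    def test_budget_equal_to_initial_size_single_fit(self, unit_space_2d, rng):
        state, _ = adaptive_sample(
            lambda x: float(np.sin(5 * x[0]) * x[1]),
            unit_space_2d,
            lambda X, Y: fit_kriging(X, Y, bounds=unit_space_2d.bounds, seed=0),
            theta=1e-12,
            budget=10,
            n_initial=10,
            seed=5,
        )
        assert len(state.eps_loo_history) == 1
        assert state.stop_reason == "budget exhausted"
        assert state.n == 10

    def test_enrichment_respects_bounds_and_no_duplicates(self, unit_space_2d):
        state, _ = adaptive_sample(
            lambda x: float(np.sin(7 * x[0]) + x[1] ** 3),
            unit_space_2d,
            lambda X, Y: fit_kriging(X, Y, bounds=unit_space_2d.bounds, seed=0),
            theta=1e-10,
            budget=20,
            seed=2,
        )
        assert unit_space_2d.contains(state.X).all()
        d = np.sqrt(
            ((state.X[:, None] - state.X[None]) ** 2).sum(-1)
            + np.eye(state.n) * 10
        )
        assert d.min() > 1e-12
        assert state.n <= 20
        # best-so-far eps_LOO is non-increasing by construction
        assert np.all(np.diff(state.best_eps_history) <= 0)

    def test_reproducible_under_master_seed(self, unit_space_2d):
        runs = [
            adaptive_sample(
                lambda x: float(np.exp(x[0]) * x[1]),
                unit_space_2d,
                lambda X, Y: fit_kriging(X, Y, bounds=unit_space_2d.bounds, seed=0),
                theta=1e-8,
                budget=16,
                seed=9,
            )[0]
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].X, runs[1].X)
        assert runs[0].eps_loo_history == runs[1].eps_loo_history

    def test_failing_model_points_are_rejected_and_logged(self, unit_space_2d):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if 0.45 < x[0] < 0.55 and calls["n"] > 10:
                raise RuntimeError("solver diverged")
            return float(x[0] + x[1])

        state, _ = adaptive_sample(
            flaky,
            unit_space_2d,
            lambda X, Y: fit_kriging(X, Y, bounds=unit_space_2d.bounds, seed=0),
            theta=1e-14,
            budget=14,
            seed=3,
        )
        # loop completed despite failures; any rejections were recorded
        assert state.n <= 14
        for rec in state.rejected:
            assert "solver diverged" in rec["error"]

    def test_budget_smaller_than_initial_rejected(self, unit_space_2d):
        with pytest.raises(ValueError):
            adaptive_sample(
                self._linear, unit_space_2d, lambda X, Y: None, budget=5, seed=0
            )
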