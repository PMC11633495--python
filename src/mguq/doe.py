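"""Design of computer experiments: one-shot samplers and adaptive enrichment.

One-shot designs (Monte Carlo, Latin hypercube, Sobol and Halton sequences)
draw a fixed number of points from the uniform parametric space in one go;
the conventional minimum size is ten points per uncertain parameter plus
two.  The adaptive strategy starts from a small Latin hypercube, fits a
surrogate, and greedily enriches the design with a constrained min-max
(CMM) learning function -- the candidate maximising the minimum distance to
the existing design, restricted to the upper quartile of predictive
variance when the surrogate provides one -- until the normalised
leave-one-out error drops below a threshold, the budget is exhausted, or
enrichment stops improving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

_METHODS = ("mc", "lhs", "sobol", "halton")


@dataclass
class ParameterSpace:
    """Named uncertain parameters, each uniform on its scaled interval.

    Each parameter is ``(name, lower, upper)``.  ``scales`` selects, per
    parameter, the scale on which the uniform distribution lives:

    * ``"linear"`` -- uniform on [lower, upper];
    * ``"log"`` -- uniform on the decade (log-magnitude) scale between
      the two bounds.  Bounds must share a sign (rate constants keep the
      sign of their tabulated values; the magnitude is log-uniform).

    Wide kinetic ranges printed as powers of ten are log-scaled: a
    calibrated optimum such as 6e-9 inside [1e-12, 1e-4] occupies a
    resolvable region of the design space only on that scale.
    """

    params: Sequence[tuple[str, float, float]]
    scales: Sequence[str] | None = None

    def __post_init__(self) -> None:
        names = [p[0] for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if self.scales is None:
            self.scales = ["linear"] * len(self.params)
        self.scales = list(self.scales)
        if len(self.scales) != len(self.params):
            raise ValueError("one scale per parameter required")
        for (name, lo, hi), scale in zip(self.params, self.scales):
            if scale not in ("linear", "log"):
                raise ValueError(f"unknown scale {scale!r} for {name}")
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo == hi:
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")
            if scale == "linear" and not lo < hi:
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")
            if scale == "log" and (lo * hi <= 0):
                raise ValueError(f"log-scaled {name} needs sign-consistent nonzero bounds")

    @property
    def names(self) -> list[str]:
        return [p[0] for p in self.params]

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def bounds(self) -> np.ndarray:
        """Physical bounds as an (n_params, 2) array, [min, max] per row."""
        b = np.array([[p[1], p[2]] for p in self.params], dtype=float)
        return np.column_stack([b.min(axis=1), b.max(axis=1)])

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Map physical points to the unit hypercube of the sampling scale."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        u = np.empty_like(x)
        for j, ((_, lo, hi), scale) in enumerate(zip(self.params, self.scales)):
            if scale == "linear":
                u[:, j] = (x[:, j] - lo) / (hi - lo)
            else:
                llo, lhi = np.log10(abs(lo)), np.log10(abs(hi))
                u[:, j] = (np.log10(np.abs(x[:, j])) - llo) / (lhi - llo)
        return u

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_unit` (restores tabulated signs)."""
        u = np.atleast_2d(np.asarray(u, dtype=float))
        x = np.empty_like(u)
        for j, ((_, lo, hi), scale) in enumerate(zip(self.params, self.scales)):
            if scale == "linear":
                x[:, j] = lo + u[:, j] * (hi - lo)
            else:
                llo, lhi = np.log10(abs(lo)), np.log10(abs(hi))
                x[:, j] = np.sign(lo) * 10.0 ** (llo + u[:, j] * (lhi - llo))
        return x

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        u = self.to_unit(x)
        return np.all((u >= -atol) & (u <= 1 + atol), axis=1)

    def to_dict(self) -> dict:
        return {"params": [list(p) for p in self.params], "scales": list(self.scales)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        return cls(
            params=[tuple(p) for p in d["params"]], scales=d.get("scales")
        )


@dataclass
class DesignMatrix:
    """Sampled input points in physical units, with provenance."""

    points: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class AdaptiveState:
    """Design, responses and stopping history of one adaptive run."""

    X: np.ndarray
    Y: np.ndarray
    eps_loo_history: list[float] = field(default_factory=list)
    n_initial: int = 0
    theta: float = 1e-4
    budget: int = 0
    stop_reason: str = ""
    rejected: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def best_eps_history(self) -> np.ndarray:
        """Best-so-far (non-increasing) leave-one-out error trace."""
        return np.minimum.accumulate(self.eps_loo_history)


def min_one_shot_size(n_params: int) -> int:
    """Minimum one-shot design size: 10 * n_params + 2."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return 10 * int(n_params) + 2


def sample_one_shot(
    space: ParameterSpace, n: int, method: str = "lhs", seed: int | None = None
) -> DesignMatrix:
    """Draw an n-point one-shot design with the requested sampler.

    ``method`` is one of ``mc`` (plain Monte Carlo), ``lhs`` (stratified
    Latin hypercube: one point per marginal stratum), ``sobol`` or
    ``halton`` (quasi-random sequences; scrambled only when a seed is
    given so that the unseeded designs remain the canonical sequences).
    Fixed seeds yield identical designs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    method = method.lower()
    d = space.n_params
    if method == "mc":
        rng = np.random.default_rng(seed)
        u = rng.random((n, d))
    elif method == "lhs":
        u = qmc.LatinHypercube(d, seed=seed).random(n)
    elif method == "sobol":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # n not a power of 2 is fine here
            u = qmc.Sobol(d, scramble=seed is not None, seed=seed).random(n)
    elif method == "halton":
        u = qmc.Halton(d, scramble=seed is not None, seed=seed).random(n)
    else:
        raise ValueError(f"unknown sampling method {method!r}; use one of {_METHODS}")
    return DesignMatrix(points=space.from_unit(u), method=method, seed=seed)


def cmm_select(
    candidate_pool: np.ndarray,
    existing_design: np.ndarray,
    space: ParameterSpace,
    surrogate=None,
) -> int:
    """Constrained min-max selection: index of the best pool candidate.

    Maximises the minimum Euclidean distance (unit-scaled coordinates) to
    the existing design.  When ``surrogate`` exposes ``predict(X,
    return_var=True)``, candidates are first restricted to the upper
    quartile of predictive variance.  Ties break to the lowest index.
    """
    pool = np.atleast_2d(candidate_pool)
    if pool.shape[0] == 0:
        raise ValueError("candidate pool is empty")
    u_pool = space.to_unit(pool)
    u_design = space.to_unit(np.atleast_2d(existing_design))

    active = np.arange(pool.shape[0])
    if surrogate is not None:
        try:
            _, var = surrogate.predict(pool, return_var=True)
        except TypeError:
            var = None
        if var is not None and np.ptp(var) > 0:
            cut = np.quantile(var, 0.75)
            sel = np.flatnonzero(var >= cut)
            if sel.size:
                active = sel
    d2 = ((u_pool[active, None, :] - u_design[None, :, :]) ** 2).sum(axis=2)
    min_dist = np.sqrt(d2.min(axis=1))
    return int(active[np.argmax(min_dist)])


def adaptive_sample(
    model_fn: Callable[[np.ndarray], float],
    space: ParameterSpace,
    surrogate_factory: Callable[[np.ndarray, np.ndarray], object],
    theta: float = 1e-4,
    budget: int = 100,
    n_initial: int | None = None,
    patience: int = 10,
    rel_improvement: float = 0.01,
    pool_size: int | None = None,
    seed: int | None = None,
) -> tuple[AdaptiveState, object]:
    """Adaptive design loop: fit, check eps_LOO, enrich with CMM, repeat.

    Parameters
    ----------
    model_fn : callable
        Maps one parameter vector (1-D array) to a scalar response.
        Failures (exceptions or non-finite output) reject the point; the
        loop continues with the next CMM candidate.
    surrogate_factory : callable
        ``factory(X, Y) -> model`` returning a fitted surrogate exposing
        ``loo_error_`` (normalised leave-one-out error) and ``predict``.
    theta : float
        Stopping threshold on eps_LOO.
    budget : int
        Maximum number of model evaluations (design size).
    n_initial : int, optional
        Initial Latin-hypercube size; defaults to 5 points per parameter.
    patience, rel_improvement :
        Enrichment stops when the best eps_LOO has not improved by at
        least ``rel_improvement`` (relative) over the last ``patience``
        enrichment iterations.
    pool_size : int, optional
        Fresh LHS candidate-pool size per iteration (default 100 * d).

    Returns
    -------
    (AdaptiveState, fitted surrogate)
    """
    d = space.n_params
    if n_initial is None:
        n_initial = 5 * d
    if budget < n_initial:
        raise ValueError("budget must be at least the initial design size")
    if pool_size is None:
        pool_size = 100 * d

    ss = np.random.SeedSequence(seed)
    init_seed, pool_seed0 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    X = sample_one_shot(space, n_initial, "lhs", seed=init_seed).points
    Y = np.array([float(model_fn(x)) for x in X])

    state = AdaptiveState(
        X=X, Y=Y, n_initial=n_initial, theta=theta, budget=budget, seed=seed
    )
    best = np.inf
    best_iter = 0
    iteration = 0
    model = surrogate_factory(X, Y)
    while True:
        eps = float(model.loo_error_)
        state.eps_loo_history.append(eps)
        if eps < best * (1 - rel_improvement):
            best = eps
            best_iter = iteration
        if eps < theta:
            state.stop_reason = "eps_loo < theta"
            break
        if X.shape[0] >= budget:
            state.stop_reason = "budget exhausted"
            break
        if iteration - best_iter >= patience:
            state.stop_reason = "no improvement"
            break

        pool = sample_one_shot(
            space, pool_size, "lhs", seed=(pool_seed0 + iteration) % (2**31)
        ).points
        accepted = False
        for _ in range(pool.shape[0]):
            j = cmm_select(pool, X, space, surrogate=model)
            x_new = pool[j]
            try:
                y_new = float(model_fn(x_new))
                if not np.isfinite(y_new):
                    raise ValueError("non-finite model response")
            except Exception as exc:  # noqa: BLE001 - point rejection contract
                state.rejected.append({"x": x_new.tolist(), "error": str(exc)})
                pool = np.delete(pool, j, axis=0)
                if pool.shape[0] == 0:
                    break
                continue
            # skip near-duplicates (scaled distance below 1e-12)
            u = space.to_unit(x_new)[0]
            if np.min(((space.to_unit(X) - u) ** 2).sum(axis=1)) < 1e-24:
                pool = np.delete(pool, j, axis=0)
                if pool.shape[0] == 0:
                    break
                continue
            X = np.vstack([X, x_new])
            Y = np.append(Y, y_new)
            accepted = True
            break
        if not accepted:
            state.stop_reason = "candidate pool exhausted"
            break
        state.X, state.Y = X, Y
        iteration += 1
        model = surrogate_factory(X, Y)

    state.X, state.Y = X, Y
    return state, model
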