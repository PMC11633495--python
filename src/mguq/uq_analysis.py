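"""Forward UQ on fitted surrogates: Sobol indices, propagation, calibration.

Sobol sensitivity indices are computed on two routes.  For PCE (and the
PCE trend of a PC-Kriging model) the indices follow analytically from the
orthonormal coefficients:

    S_i   = sum_{alpha: alpha_i > 0, alpha_j = 0 (j != i)} y_alpha^2 / D
    S_T,i = sum_{alpha: alpha_i > 0} y_alpha^2 / D
    D     = sum_{alpha != 0} y_alpha^2.

For black-box surrogates (Kriging) a Saltelli/Janon pick-freeze Monte
Carlo estimator is used, with bootstrap error bars.

Uncertainty propagation pushes a Latin-hypercube sample of the uniform
parameter box through a model and summarises the output distribution.
Calibration minimises the NRMSE between surrogate predictions and
observations over the bounded space: a seeded LHS screen followed by
Nelder-Mead refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from mguq.doe import ParameterSpace, sample_one_shot
from mguq.surrogates.metrics import nrmse
from mguq.surrogates.pce import PCEModel
from mguq.surrogates.pck import PCKModel


@dataclass
class SobolIndices:
    """First-order and total Sobol indices per parameter."""

    first_order: np.ndarray
    total: np.ndarray
    param_names: list[str] | None = None
    estimator: str = "analytic-pce"
    se_first: np.ndarray | None = None
    se_total: np.ndarray | None = None
    n_samples: int | None = None

    def to_frame(self):
        import pandas as pd

        names = self.param_names or [f"x{i}" for i in range(len(self.first_order))]
        data = {"param": names, "S": self.first_order, "S_T": self.total}
        if self.se_first is not None:
            data["se_S"] = self.se_first
            data["se_S_T"] = self.se_total
        return pd.DataFrame(data)


@dataclass
class PropagationResult:
    """Summary of an output distribution under input uncertainty."""

    mean: float
    variance: float
    quantiles: dict[float, float]
    n_samples: int
    seed: int | None
    samples: np.ndarray | None = None


@dataclass
class CalibrationResult:
    """Outcome of surrogate-based parameter estimation."""

    params: dict[str, float]
    objective: float
    trace: list[dict] = field(default_factory=list)
    surrogate: str = ""

    @property
    def x(self) -> np.ndarray:
        return np.array(list(self.params.values()))


def sobol_from_pce(model: PCEModel | PCKModel, param_names=None) -> SobolIndices:
    """Analytic Sobol indices from orthonormal PCE coefficients.

    A PC-Kriging model contributes through its polynomial trend (the
    stochastic residual is parameter-independent in distribution).
    Raises for a constant expansion (zero variance).
    """
    if isinstance(model, PCKModel):
        model = model.as_pce()
    alphas = model.index_set
    coefs = model.coefficients
    nonconst = alphas.sum(axis=1) > 0
    D = float((coefs[nonconst] ** 2).sum())
    if D == 0:
        raise ValueError("constant PCE: Sobol indices undefined")
    d = alphas.shape[1]
    first = np.zeros(d)
    total = np.zeros(d)
    for i in range(d):
        has_i = alphas[:, i] > 0
        only_i = has_i & (np.delete(alphas, i, axis=1).sum(axis=1) == 0)
        first[i] = (coefs[only_i] ** 2).sum() / D
        total[i] = (coefs[has_i] ** 2).sum() / D
    return SobolIndices(
        first_order=first, total=total, param_names=param_names, estimator="analytic-pce"
    )


def _model_eval(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict"):
        return np.asarray(model.predict(X), dtype=float).ravel()
    return np.asarray([float(model(x)) for x in np.atleast_2d(X)], dtype=float)


def sobol_mc(
    model_fn,
    space: ParameterSpace,
    n: int = 1024,
    seed: int | None = None,
    n_boot: int = 200,
) -> SobolIndices:
    """Pick-freeze (Saltelli-type) Monte Carlo Sobol estimator.

    Uses two independent input matrices A, B and the hybrid matrices AB_i;
    first-order indices by the Janon estimator, total indices by Jansen's
    formula.  Small negative estimates are reported as-is, with bootstrap
    (over sample rows) standard errors.
    """
    if n < 64:
        raise ValueError("n must be at least 64")
    d = space.n_params
    rng = np.random.default_rng(seed)
    A = space.from_unit(rng.random((n, d)))
    B = space.from_unit(rng.random((n, d)))
    fA = _model_eval(model_fn, A)
    fB = _model_eval(model_fn, B)
    fAB = np.empty((d, n))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = _model_eval(model_fn, ABi)

    def estimate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b, ab = fA[idx], fB[idx], fAB[:, idx]
        var = np.concatenate([a, b]).var()
        if var == 0:
            return np.zeros(d), np.zeros(d)
        # Janon first-order estimator
        mean2 = (0.5 * (b + ab)).mean(axis=1) ** 2
        S = ((b * ab).mean(axis=1) - mean2) / (
            (0.5 * (b**2 + ab**2)).mean(axis=1) - mean2
        )
        ST = 0.5 * ((a[None, :] - ab) ** 2).mean(axis=1) / var
        return S, ST

    full = np.arange(n)
    S, ST = estimate(full)
    boots_S = np.empty((n_boot, d))
    boots_T = np.empty((n_boot, d))
    for b_i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots_S[b_i], boots_T[b_i] = estimate(idx)
    return SobolIndices(
        first_order=S,
        total=ST,
        param_names=space.names,
        estimator="mc-pick-freeze",
        se_first=boots_S.std(axis=0),
        se_total=boots_T.std(axis=0),
        n_samples=n,
    )


def propagate(
    model,
    space: ParameterSpace,
    n: int = 1000,
    seed: int | None = None,
    quantiles: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
    keep_samples: bool = False,
) -> PropagationResult:
    """Push an LHS input sample through the model; summarise the output.

    Aborts if more than 10% of evaluations fail (non-finite output).
    """
    design = sample_one_shot(space, n, "lhs", seed=seed)
    y = _model_eval(model, design.points)
    ok = np.isfinite(y)
    if ok.mean() < 0.9:
        raise RuntimeError(
            f"model failure rate {100 * (1 - ok.mean()):.1f}% exceeds 10%"
        )
    y = y[ok]
    qs = {float(q): float(np.quantile(y, q)) for q in quantiles}
    return PropagationResult(
        mean=float(y.mean()),
        variance=float(y.var(ddof=1)) if y.size > 1 else 0.0,
        quantiles=qs,
        n_samples=int(y.size),
        seed=seed,
        samples=y if keep_samples else None,
    )


def _calibration_objective(predict_obs: Callable[[np.ndarray], Mapping[str, np.ndarray]],
                           observed: Mapping[str, np.ndarray]) -> Callable[[np.ndarray], float]:
    def objective(x: np.ndarray) -> float:
        pred = predict_obs(np.atleast_2d(x))
        vals = []
        for key, y_ref in observed.items():
            p = np.asarray(pred[key], dtype=float).ravel()
            if not np.all(np.isfinite(p)):
                return np.inf
            vals.append(nrmse(p, y_ref))
        return float(np.mean(vals))

    return objective


def calibrate(
    surrogate_set,
    observed,
    space: ParameterSpace,
    n_screen: int = 1000,
    seed: int | None = None,
    surrogate_name: str = "",
) -> CalibrationResult:
    """Estimate model parameters by minimising NRMSE against observations.

    Parameters
    ----------
    surrogate_set :
        Either a single object with ``predict_at``/``predict`` mapping a
        parameter matrix to predictions at the observed points, or a dict
        ``{qoi_name: surrogate}``; multi-QoI objectives average the
        per-QoI NRMSE with equal weights.
    observed :
        ``TimeSeriesOutput`` (single QoI) or dict ``{qoi_name:
        (surrogate-prediction-target values)}`` aligned with the
        surrogates' prediction output.
    space :
        Uniform parameter box; the optimum is constrained to it.

    A seeded LHS screen of ``n_screen`` points is followed by Nelder-Mead
    refinement (clipped to bounds).  The returned objective is never worse
    than the best screened point.
    """
    # normalise inputs to {name: (predict_fn, y_ref)}
    from mguq.degradation_models.outputs import TimeSeriesOutput

    if isinstance(observed, TimeSeriesOutput):
        observed = {"qoi": observed}
        surrogate_set = {"qoi": surrogate_set}

    y_refs: dict[str, np.ndarray] = {}
    predictors: dict[str, Callable[[np.ndarray], np.ndarray]] = {}
    for key, obs in observed.items():
        sur = surrogate_set[key]
        if isinstance(obs, TimeSeriesOutput):
            times = obs.times
            y_refs[key] = obs.values
            if hasattr(sur, "predict_at"):
                predictors[key] = lambda X, s=sur, t=times: s.predict_at(X, t)
            else:
                predictors[key] = lambda X, s=sur: np.atleast_1d(s.predict(X))
        else:
            y_refs[key] = np.asarray(obs, dtype=float).ravel()
            predictors[key] = lambda X, s=sur: np.atleast_1d(s.predict(X))

    def predict_obs(X: np.ndarray) -> dict[str, np.ndarray]:
        return {key: fn(X) for key, fn in predictors.items()}

    objective = _calibration_objective(predict_obs, y_refs)

    screen = sample_one_shot(space, n_screen, "lhs", seed=seed).points
    vals = np.array([objective(x) for x in screen])
    if not np.any(np.isfinite(vals)):
        raise RuntimeError("all screened predictions are non-finite")
    best_idx = int(np.nanargmin(vals))
    x0 = screen[best_idx]
    trace = [{"stage": "screen", "x": x0.tolist(), "objective": float(vals[best_idx])}]

    # refine in the (scale-aware) unit coordinates of the space, so that
    # log-scaled parameters are searched on their decade scale
    def unit_objective(u: np.ndarray) -> float:
        return objective(space.from_unit(np.clip(u, 0.0, 1.0))[0])

    res = minimize(
        unit_objective,
        x0=space.to_unit(x0)[0],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    x_opt = space.from_unit(np.clip(res.x, 0.0, 1.0))[0]
    f_opt = objective(x_opt)
    if f_opt > vals[best_idx]:  # refinement must never lose to the screen
        x_opt, f_opt = x0, float(vals[best_idx])
    trace.append({"stage": "nelder-mead", "x": x_opt.tolist(), "objective": float(f_opt)})
    return CalibrationResult(
        params=dict(zip(space.names, x_opt.tolist())),
        objective=float(f_opt),
        trace=trace,
        surrogate=surrogate_name,
    )
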