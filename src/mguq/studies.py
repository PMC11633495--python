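"""Reproducible adaptive-sampling studies on the three case models.

These bind the case QoIs, the surrogate fitters and the adaptive-design
loop into single-call studies used by the validation suite and the
result-reproduction script.
"""

from __future__ import annotations

import numpy as np

from mguq.cases import CASES
from mguq.doe import AdaptiveState, adaptive_sample
from mguq.surrogates import fit_kriging, fit_pce, fit_pck


def _fitter(surrogate: str, space, seed: int):
    surrogate = surrogate.lower()
    if surrogate == "kriging":
        return lambda X, Y: fit_kriging(X, Y, space=space, seed=seed)
    if surrogate == "pce":
        return lambda X, Y: fit_pce(X, Y, space=space)
    if surrogate == "pck":
        return lambda X, Y: fit_pck(X, Y, space=space, seed=seed)
    raise ValueError(f"unknown surrogate {surrogate!r}")


def adaptive_study(
    model_id: int,
    surrogate: str,
    seed: int,
    theta: float = 1e-4,
    budget: int = 80,
    n_initial: int | None = None,
) -> AdaptiveState:
    """One adaptive-sampling run for a case model and surrogate family."""
    case = CASES[model_id]
    space = case["space"]()
    state, _ = adaptive_sample(
        case["qoi"],
        space,
        _fitter(surrogate, space, 0),
        theta=theta,
        budget=budget,
        n_initial=n_initial,
        seed=seed,
    )
    return state


def terminal_count_median(
    model_id: int,
    surrogate: str,
    seeds,
    theta: float = 1e-4,
    budget: int = 80,
) -> tuple[float, list[int]]:
    """Median terminal design size over replicate seeds."""
    counts = [
        adaptive_study(model_id, surrogate, int(s), theta=theta, budget=budget).n
        for s in seeds
    ]
    return float(np.median(counts)), counts
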