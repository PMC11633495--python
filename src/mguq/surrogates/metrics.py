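"""Surrogate validation metrics and per-time-point surrogate bundles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


def nrmse(pred: np.ndarray, y_ref: np.ndarray) -> float:
    """Root-mean-square error normalised by the reference range.

    ``sqrt(mean((y_ref - pred)^2)) / (max(y_ref) - min(y_ref))``; raises
    for a constant reference (zero range).
    """
    pred = np.asarray(pred, dtype=float).ravel()
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if pred.shape != y_ref.shape or pred.size < 1:
        raise ValueError("pred and y_ref must have the same nonzero length")
    span = y_ref.max() - y_ref.min()
    if span <= 0:
        raise ValueError("reference data is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((y_ref - pred) ** 2)) / span)


def eps_loo(
    surrogate_factory: Callable[[np.ndarray, np.ndarray], object],
    X: np.ndarray,
    Y: np.ndarray,
    k: int | None = None,
) -> float:
    """Normalised cross-validation error by explicit refits.

    Splits the data into ``k`` folds (default k = N, i.e. true
    leave-one-out), refits the surrogate on each training portion, and
    returns mean((M(x_i) - M_(-i)(x_i))^2) / Var(Y).  This is the
    brute-force counterpart of the closed-form ``loo_error_`` the fitted
    surrogates expose; the two agree for linear fits and fixed
    hyperparameters.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    n = len(Y)
    if n < 3:
        raise ValueError("need at least three points for cross-validation")
    var_y = Y.var()
    if np.ptp(Y) == 0 or var_y < 1e-24 * (np.abs(Y).max() ** 2 + 1e-300):
        warnings.warn("constant response: eps_LOO defined as 0", RuntimeWarning, stacklevel=2)
        return 0.0
    if k is None:
        k = n
    if not (2 <= k <= n):
        raise ValueError("k must be between 2 and N")
    folds = np.array_split(np.arange(n), k)
    se = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = surrogate_factory(X[mask], Y[mask])
        pred = np.atleast_1d(model.predict(X[fold]))
        se[fold] = (Y[fold] - pred) ** 2
    return float(se.mean() / var_y)


@dataclass
class TimeGridSurrogate:
    """One independent surrogate per output time point.

    Emulates a time-resolved QoI by bundling scalar surrogates fitted to
    the response at each time on a fixed grid.
    """

    times: np.ndarray
    models: list

    def __post_init__(self) -> None:
        if len(self.models) != len(self.times):
            raise ValueError("one model per time point required")

    @property
    def loo_error_(self) -> float:
        """Worst-case eps_LOO across the grid (conservative summary)."""
        return float(max(m.loo_error_ for m in self.models))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions with shape (n_points, n_times)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([np.atleast_1d(m.predict(X)) for m in self.models])

    def predict_at(self, X: np.ndarray, t_days: Sequence[float]) -> np.ndarray:
        """Predictions restricted to a subset of the time grid."""
        t_days = np.asarray(t_days, dtype=float)
        cols = []
        for t in t_days:
            j = int(np.argmin(np.abs(self.times - t)))
            if abs(self.times[j] - t) > 1e-9:
                raise ValueError(f"time {t} not on the surrogate grid")
            cols.append(j)
        return self.predict(X)[:, cols]


def fit_time_grid(
    fit_fn: Callable[[np.ndarray, np.ndarray], object],
    X: np.ndarray,
    Y_grid: np.ndarray,
    times: Sequence[float],
) -> TimeGridSurrogate:
    """Fit one scalar surrogate per column of ``Y_grid`` (n_points, n_times)."""
    Y_grid = np.atleast_2d(np.asarray(Y_grid, dtype=float))
    times = np.asarray(times, dtype=float)
    if Y_grid.shape[1] != times.shape[0]:
        raise ValueError("Y_grid must have one column per time point")
    models = [fit_fn(X, Y_grid[:, j]) for j in range(times.shape[0])]
    return TimeGridSurrogate(times=times, models=models)
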