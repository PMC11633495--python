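"""Universal Kriging (Gaussian-process regression) with Matérn 5/2 kernel.

The predictor is the best linear unbiased prediction (BLUP)

    M(x) = f(x)' beta + r(x)' R^{-1} (y - F beta)

with trend functions f (a constant by default, or a PCE basis for
PC-Kriging), anisotropic lengthscales theta_j per input dimension,
process variance sigma^2, and the Matérn 5/2 correlation.  Lengthscales
are estimated by profiled maximum likelihood with multi-start bounded
quasi-Newton optimisation on log-lengthscales; beta and sigma^2 follow
from their closed-form generalised-least-squares profiles.  A small
nugget (1e-10, escalated on failure) regularises the Cholesky
factorisation, so the model interpolates noise-free data to within
1e-6 of the response range.

Leave-one-out residuals use the closed form for universal Kriging via the
bordered correlation matrix (Dubrule's cross-validation identities):
with B = [[R, F], [F', 0]] and [alpha; gamma] = B^{-1} [y; 0], the LOO
error at x_i is alpha_i / (B^{-1})_ii at fixed hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

_SQRT5 = np.sqrt(5.0)


def matern52(r: np.ndarray | float, theta: float = 1.0) -> np.ndarray | float:
    """Matérn 5/2 correlation: (1 + s + s^2/3) exp(-s), s = sqrt(5) r / theta."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    if theta <= 0:
        raise ValueError("theta must be positive")
    s = _SQRT5 * r / theta
    out = (1.0 + s + s**2 / 3.0) * np.exp(-s)
    return float(out) if out.ndim == 0 else out


def _scaled_dist(A: np.ndarray, B: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return cdist(A / theta, B / theta)


@dataclass
class KrigingModel:
    """A fitted universal Kriging surrogate."""

    X_train: np.ndarray  # physical units
    y_train: np.ndarray
    bounds: np.ndarray
    space: object | None  # optional ParameterSpace for scale-aware input maps
    theta: np.ndarray  # lengthscales in unit-scaled coordinates
    beta: np.ndarray
    sigma2: float
    nugget: float
    trend: object  # "constant" or an object with basis_eval
    loo_error_: float = np.inf
    _chol: np.ndarray | None = field(default=None, repr=False)
    _gamma: np.ndarray | None = field(default=None, repr=False)  # R^-1 (y - F beta)
    _Fmat: np.ndarray | None = field(default=None, repr=False)
    _RinvF: np.ndarray | None = field(default=None, repr=False)

    def _to_unit(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.space is not None:
            return self.space.to_unit(X)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return (X - lo) / (hi - lo)

    def _trend_matrix(self, X: np.ndarray) -> np.ndarray:
        if isinstance(self.trend, str) and self.trend == "constant":
            return np.ones((np.atleast_2d(X).shape[0], 1))
        if hasattr(self.trend, "basis_eval"):
            return self.trend.basis_eval(X)
        return np.atleast_2d(self.trend(X))

    def predict(self, X: np.ndarray, return_var: bool = False):
        U = self._to_unit(X)
        Ut = self._to_unit(self.X_train)
        r = matern52(_scaled_dist(U, Ut, self.theta))
        f = self._trend_matrix(X)
        mean = f @ self.beta + r @ self._gamma
        if not return_var:
            return mean
        # BLUP variance with trend-estimation correction
        Rinv_r = sla.cho_solve((self._chol, True), r.T)
        u = f.T - self._Fmat.T @ Rinv_r
        FtRinvF = self._Fmat.T @ self._RinvF
        mid = np.linalg.solve(FtRinvF, u)
        var = self.sigma2 * (
            1.0 + self.nugget - np.einsum("ij,ji->i", r, Rinv_r) + np.einsum("ij,ij->j", u, mid)
        )
        return mean, np.maximum(var, 0.0)

    def to_dict(self) -> dict:
        trend = "constant" if isinstance(self.trend, str) else self.trend.to_dict()
        return {
            "kind": "kriging",
            "X_train": self.X_train.tolist(),
            "y_train": self.y_train.tolist(),
            "bounds": self.bounds.tolist(),
            "space": None if self.space is None else self.space.to_dict(),
            "theta": self.theta.tolist(),
            "nugget": self.nugget,
            "trend": trend,
            "loo_error": self.loo_error_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KrigingModel":
        from mguq.surrogates.pce import PCEModel

        from mguq.doe import ParameterSpace

        trend = d["trend"]
        if trend != "constant":
            trend = PCEModel.from_dict(trend)
        space = None if d.get("space") is None else ParameterSpace.from_dict(d["space"])
        model = _assemble(
            np.array(d["X_train"], float),
            np.array(d["y_train"], float),
            np.array(d["bounds"], float),
            np.array(d["theta"], float),
            trend,
            float(d["nugget"]),
            space=space,
        )
        return model


def _profile_nll(
    theta: np.ndarray, U: np.ndarray, y: np.ndarray, F: np.ndarray, nugget: float
) -> float:
    n = U.shape[0]
    R = matern52(_scaled_dist(U, U, theta))
    R[np.diag_indices_from(R)] += nugget
    try:
        c = sla.cholesky(R, lower=True)
    except sla.LinAlgError:
        return 1e30
    Rinv_y = sla.cho_solve((c, True), y)
    Rinv_F = sla.cho_solve((c, True), F)
    FtRF = F.T @ Rinv_F
    try:
        beta = np.linalg.solve(FtRF, F.T @ Rinv_y)
    except np.linalg.LinAlgError:
        return 1e30
    res = y - F @ beta
    sigma2 = float(res @ sla.cho_solve((c, True), res)) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return 0.5 * (n * np.log(sigma2) + logdet)


def _assemble(X, y, bounds, theta, trend, nugget, space=None) -> KrigingModel:
    model = KrigingModel(
        X_train=X, y_train=y, bounds=bounds, space=space, theta=theta,
        beta=np.zeros(1), sigma2=1.0, nugget=nugget, trend=trend,
    )
    U = model._to_unit(X)
    F = model._trend_matrix(X)
    R = matern52(_scaled_dist(U, U, theta))
    R[np.diag_indices_from(R)] += nugget
    c = sla.cholesky(R, lower=True)
    Rinv_y = sla.cho_solve((c, True), y)
    Rinv_F = sla.cho_solve((c, True), F)
    beta = np.linalg.solve(F.T @ Rinv_F, F.T @ Rinv_y)
    res = y - F @ beta
    gamma = sla.cho_solve((c, True), res)
    sigma2 = float(res @ gamma) / len(y)
    model.beta = beta
    model.sigma2 = max(sigma2, 0.0)
    model._chol = c
    model._gamma = gamma
    model._Fmat = F
    model._RinvF = Rinv_F
    model.loo_error_ = _loo_closed_form(R, F, y)
    return model


def _loo_closed_form(R: np.ndarray, F: np.ndarray, y: np.ndarray) -> float:
    """Normalised LOO error from the bordered-matrix identities."""
    n, m = F.shape
    if n <= m + 1:
        return np.inf
    B = np.block([[R, F], [F.T, np.zeros((m, m))]])
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError:
        return np.inf
    alpha = Binv[:n] @ np.concatenate([y, np.zeros(m)])
    dii = np.diag(Binv)[:n]
    if np.any(np.abs(dii) < 1e-300):
        return np.inf
    var_y = y.var()
    if np.ptp(y) == 0 or var_y < 1e-24 * (np.abs(y).max() ** 2 + 1e-300):
        return 0.0
    e = alpha / dii
    return float(np.mean(e**2) / var_y)


def fit_kriging(
    X: np.ndarray,
    Y: np.ndarray,
    trend="constant",
    bounds: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    n_starts: int = 5,
    nugget: float = 1e-10,
    theta_bounds: tuple[float, float] = (1e-2, 5.0),
    seed: int = 0,
    optimize: bool = True,
    space=None,
) -> KrigingModel:
    """Fit a Kriging surrogate by profiled maximum likelihood.

    ``trend`` is ``"constant"`` (ordinary Kriging), an object exposing
    ``basis_eval`` (e.g. a fitted PCE, giving PC-Kriging), or a callable
    returning the trend matrix.  Lengthscales live in unit-scaled
    coordinates and are optimised on a log scale from ``n_starts`` seeded
    starting points; pass ``theta0`` with ``optimize=False`` to fix them.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    n, d = X.shape
    if n < 2:
        raise ValueError("at least two training points are required")
    if np.unique(X, axis=0).shape[0] < n:
        raise ValueError("degenerate design: duplicated training points")
    if space is not None:
        bounds = np.tile([0.0, 1.0], (d, 1))
    elif bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        bounds = np.column_stack([lo, lo + span])
    bounds = np.asarray(bounds, dtype=float)

    probe = KrigingModel(
        X_train=X, y_train=Y, bounds=bounds, space=space, theta=np.ones(d),
        beta=np.zeros(1), sigma2=1.0, nugget=nugget, trend=trend,
    )
    U = probe._to_unit(X)
    F = probe._trend_matrix(X)
    if F.shape[1] >= n:
        raise ValueError("trend basis must be smaller than the training set")

    lb, ub = np.log10(theta_bounds[0]), np.log10(theta_bounds[1])
    if theta0 is not None and not optimize:
        best_theta = np.asarray(theta0, dtype=float)
    else:
        rng = np.random.default_rng(seed)
        starts = [np.zeros(d) if theta0 is None else np.log10(np.asarray(theta0))]
        starts += list(rng.uniform(lb, ub, size=(max(0, n_starts - 1), d)))
        best_val, best_theta = np.inf, np.ones(d)
        for s in starts:
            res = minimize(
                lambda lt: _profile_nll(10.0**lt, U, Y, F, nugget),
                x0=np.clip(s, lb, ub),
                method="L-BFGS-B",
                bounds=[(lb, ub)] * d,
            )
            if res.fun < best_val:
                best_val, best_theta = res.fun, 10.0**res.x

    last_err: Exception | None = None
    for nug in (nugget, 1e-8, 1e-6):
        if nug < nugget:
            continue
        try:
            return _assemble(X, Y, bounds, best_theta, trend, nug, space=space)
        except sla.LinAlgError as exc:  # escalate the nugget
            last_err = exc
    raise RuntimeError("correlation matrix singular even with nugget 1e-6") from last_err
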