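"""Polynomial chaos expansion with orthonormal Legendre basis.

Inputs are assumed uniform on a box; each dimension is affinely mapped to
[-1, 1], where the orthonormal Legendre polynomials psi_k = sqrt(2k+1) P_k
form a complete basis with respect to the uniform measure.  Multivariate
terms are tensor products indexed by multi-indices alpha restricted to the
hyperbolic (q-norm) truncation ||alpha||_q <= p.  Coefficients are
estimated by least squares; the expansion degree is chosen adaptively as
the one minimising the normalised leave-one-out error, which for a linear
least-squares fit has the closed form

    eps_LOO = mean( (r_i / (1 - h_ii))^2 ) / Var(Y)

with r the residuals and h the leverage (hat-matrix diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as L


def build_index_set(n_dims: int, p: int, q: float = 1.0) -> np.ndarray:
    """All multi-indices with hyperbolic q-norm at most p.

    For q = 1 this is the total-degree set of size (p + n)! / (p! n!).
    Returns an ``(n_terms, n_dims)`` integer array in graded order.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")

    # enumerate the total-degree set recursively; the hyperbolic set is a
    # subset of it for q <= 1
    def rec(dims: int, deg: int):
        if dims == 1:
            for a in range(deg + 1):
                yield (a,)
        else:
            for a in range(deg + 1):
                for rest in rec(dims - 1, deg - a):
                    yield (a,) + rest

    alphas = np.array(sorted(rec(n_dims, p), key=lambda a: (sum(a), a)), dtype=int)
    if q < 1.0:
        norms = (alphas.astype(float) ** q).sum(axis=1) ** (1.0 / q)
        alphas = alphas[norms <= p + 1e-12]
    return alphas


def _legendre_orthonormal(u: np.ndarray, max_degree: int) -> np.ndarray:
    """Values of sqrt(2k+1) P_k(u) for k = 0..max_degree, shape (n, p+1)."""
    V = L.legvander(u, max_degree)
    scale = np.sqrt(2.0 * np.arange(max_degree + 1) + 1.0)
    return V * scale


@dataclass
class PCEModel:
    """A fitted polynomial chaos expansion."""

    index_set: np.ndarray
    coefficients: np.ndarray
    degree: int
    q: float
    bounds: np.ndarray  # (d, 2) box mapped to [-1, 1]^d (unit box when space set)
    space: object | None = None  # optional ParameterSpace for scale-aware inputs
    loo_error_: float = np.inf
    ridge_: float = 0.0
    degree_history: dict = field(default_factory=dict)

    @property
    def n_dims(self) -> int:
        return self.index_set.shape[1]

    def _to_std(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.space is not None:
            return 2.0 * self.space.to_unit(X) - 1.0
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return 2.0 * (X - lo) / (hi - lo) - 1.0

    def basis_eval(self, X: np.ndarray) -> np.ndarray:
        """Design matrix of the orthonormal basis at physical points X."""
        U = self._to_std(X)
        pmax = int(self.index_set.max(initial=0))
        per_dim = [_legendre_orthonormal(U[:, j], pmax) for j in range(self.n_dims)]
        psi = np.ones((U.shape[0], self.index_set.shape[0]))
        for t, alpha in enumerate(self.index_set):
            for j, a in enumerate(alpha):
                if a:
                    psi[:, t] *= per_dim[j][:, a]
        return psi

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.basis_eval(X) @ self.coefficients

    # --- variance decomposition -------------------------------------------
    @property
    def total_variance(self) -> float:
        """Output variance implied by the expansion (orthonormal basis)."""
        nonconst = self.index_set.sum(axis=1) > 0
        return float((self.coefficients[nonconst] ** 2).sum())

    def to_dict(self) -> dict:
        return {
            "kind": "pce",
            "index_set": self.index_set.tolist(),
            "coefficients": self.coefficients.tolist(),
            "degree": self.degree,
            "q": self.q,
            "bounds": self.bounds.tolist(),
            "loo_error": self.loo_error_,
            "ridge": self.ridge_,
            "space": None if self.space is None else self.space.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCEModel":
        return cls(
            index_set=np.array(d["index_set"], dtype=int),
            coefficients=np.array(d["coefficients"], dtype=float),
            degree=int(d["degree"]),
            q=float(d["q"]),
            bounds=np.array(d["bounds"], dtype=float),
            loo_error_=float(d["loo_error"]),
            ridge_=float(d.get("ridge", 0.0)),
            space=None if d.get("space") is None else _space_from_dict(d["space"]),
        )


def _ls_with_loo(psi: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares fit plus closed-form normalised LOO error.

    Falls back to a small ridge penalty when the design is
    ill-conditioned.  Returns (coefficients, eps_loo, ridge_used).
    """
    n, m = psi.shape
    ridge = 0.0
    cond = np.linalg.cond(psi)
    if cond > 1e10:
        ridge = 1e-8 * np.trace(psi.T @ psi) / m
        warnings.warn(
            "ill-conditioned PCE design matrix; using ridge fallback",
            RuntimeWarning,
            stacklevel=3,
        )
    if ridge:
        G = psi.T @ psi + ridge * np.eye(m)
        coef = np.linalg.solve(G, psi.T @ y)
        H = psi @ np.linalg.solve(G, psi.T)
        h = np.diag(H)
    else:
        coef, *_ = np.linalg.lstsq(psi, y, rcond=None)
        Q, _ = np.linalg.qr(psi)
        h = (Q**2).sum(axis=1)
    resid = y - psi @ coef
    var_y = y.var()
    if np.ptp(y) == 0 or var_y < 1e-24 * (np.abs(y).max() ** 2 + 1e-300):
        warnings.warn("constant response: eps_LOO defined as 0", RuntimeWarning, stacklevel=3)
        return coef, 0.0, ridge
    denom = 1.0 - h
    with np.errstate(divide="ignore", invalid="ignore"):
        e = resid / denom
    if np.any(denom < 1e-12) or not np.all(np.isfinite(e)):
        return coef, np.inf, ridge
    return coef, float(np.mean(e**2) / var_y), ridge


def _space_from_dict(d: dict):
    from mguq.doe import ParameterSpace

    return ParameterSpace.from_dict(d)


def fit_pce(
    X: np.ndarray,
    Y: np.ndarray,
    degree_range=range(1, 11),
    q: float = 0.75,
    bounds: np.ndarray | None = None,
    space=None,
) -> PCEModel:
    """Degree-adaptive PCE fit: lowest eps_LOO over the candidate degrees.

    Degrees whose basis is larger than the training set are skipped; at
    least one degree must be feasible.  Deterministic given (X, Y).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    n, d = X.shape
    if space is not None:
        bounds = np.tile([0.0, 1.0], (d, 1))
    elif bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        bounds = np.column_stack([lo, lo + span])
    bounds = np.asarray(bounds, dtype=float)

    best: PCEModel | None = None
    history = {}
    for p in degree_range:
        index_set = build_index_set(d, p, q)
        if index_set.shape[0] > n:
            continue
        model = PCEModel(
            index_set=index_set, coefficients=np.zeros(index_set.shape[0]),
            degree=p, q=q, bounds=bounds, space=space,
        )
        psi = model.basis_eval(X)
        coef, eps, ridge = _ls_with_loo(psi, Y)
        model.coefficients = coef
        model.loo_error_ = eps
        model.ridge_ = ridge
        history[p] = eps
        if best is None or eps < best.loo_error_:
            best = model
    if best is None:
        raise ValueError(
            "no candidate degree is feasible: the training set is smaller than "
            "the smallest basis"
        )
    best.degree_history = history
    return best
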