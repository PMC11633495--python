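"""PC-Kriging: universal Kriging with a polynomial chaos trend.

Constructed sequentially: the optimal PCE basis is selected first (by
leave-one-out error over candidate degrees), then a Kriging model is
fitted using that basis as its trend, capturing local variation the
global polynomial misses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mguq.surrogates.kriging import KrigingModel, fit_kriging
from mguq.surrogates.pce import PCEModel, fit_pce


@dataclass
class PCKModel:
    """Sequentially constructed PC-Kriging surrogate."""

    pce_trend: PCEModel
    kriging_residual: KrigingModel

    @property
    def loo_error_(self) -> float:
        return self.kriging_residual.loo_error_

    def predict(self, X: np.ndarray, return_var: bool = False):
        return self.kriging_residual.predict(X, return_var=return_var)

    @property
    def trend_coefficients(self) -> np.ndarray:
        """GLS-estimated coefficients of the PCE trend inside the Kriging fit."""
        return self.kriging_residual.beta

    def as_pce(self) -> PCEModel:
        """The PCE part with trend coefficients re-estimated by the Kriging GLS.

        Useful for analytic Sobol indices of the global (polynomial)
        component of the surrogate.
        """
        pce = PCEModel(
            index_set=self.pce_trend.index_set.copy(),
            coefficients=np.asarray(self.kriging_residual.beta, dtype=float).copy(),
            degree=self.pce_trend.degree,
            q=self.pce_trend.q,
            bounds=self.pce_trend.bounds.copy(),
            space=self.pce_trend.space,
            loo_error_=self.loo_error_,
        )
        return pce

    def to_dict(self) -> dict:
        return {
            "kind": "pck",
            "pce_trend": self.pce_trend.to_dict(),
            "kriging_residual": self.kriging_residual.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCKModel":
        return cls(
            pce_trend=PCEModel.from_dict(d["pce_trend"]),
            kriging_residual=KrigingModel.from_dict(d["kriging_residual"]),
        )


def fit_pck(
    X: np.ndarray,
    Y: np.ndarray,
    degree_range=range(1, 11),
    q: float = 0.75,
    bounds: np.ndarray | None = None,
    space=None,
    seed: int = 0,
    **kriging_kwargs,
) -> PCKModel:
    """Select the eps_LOO-optimal PCE basis, then fit Kriging on it as trend.

    The candidate degrees are additionally capped so that the trend basis
    leaves at least two degrees of freedom for the Kriging residual.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).ravel()
    n, d = X.shape
    from mguq.surrogates.pce import build_index_set

    feasible = [p for p in degree_range if build_index_set(d, p, q).shape[0] <= n - 2]
    if not feasible:
        feasible = [0]  # constant trend degenerates to ordinary Kriging
    pce = fit_pce(X, Y, degree_range=feasible, q=q, bounds=bounds, space=space)
    krig = fit_kriging(
        X, Y, trend=pce, bounds=bounds, space=space, seed=seed, **kriging_kwargs
    )
    # guard against the ML lengthscales overfitting the residual process: in
    # the short-lengthscale limit the universal-Kriging LOO equals the OLS
    # LOO of the trend itself, so PCK never cross-validates worse than its
    # PCE trend
    theta_lo = kriging_kwargs.get("theta_bounds", (1e-2, 5.0))[0]
    degenerate = fit_kriging(
        X,
        Y,
        trend=pce,
        bounds=bounds,
        space=space,
        theta0=np.full(d, theta_lo),
        optimize=False,
        **{k: v for k, v in kriging_kwargs.items() if k != "theta_bounds"},
    )
    if degenerate.loo_error_ < krig.loo_error_:
        krig = degenerate
    return PCKModel(pce_trend=pce, kriging_residual=krig)
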