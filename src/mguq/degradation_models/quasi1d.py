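"""Quasi-1D degradation of pure Mg: sigmoid-gated interface recession.

The metal/electrolyte interface recedes with normal velocity

    v_deg(t) = (M_Mg / rho_Mg) * eps * |k_deg| / (1 + exp(-(t - t_init)))

where the sigmoid (argument in days) captures the initial period of low
degradation caused by the native MgO film, followed by a linear trend once
the film has broken down.  The mean degradation depth (MDD) is the track of
the interface front, MDD(t) = integral of v_deg, starting from MDD(0) = 0
and capped at the Mg-domain length when the metal is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mguq.degradation_models.outputs import TimeSeriesOutput

DAY = 86400.0  # seconds

#: molar mass of Mg, kg/mol
M_MG = 24.305e-3
#: density of pure Mg, kg/m^3
RHO_MG = 1738.0


@dataclass
class QuasiOneDConfig:
    """Configuration of the quasi-1D pure-Mg degradation model.

    Parameters
    ----------
    epsilon : float
        Porosity of the degradation layer, in (0, 1].
    k_deg : float
        Degradation rate constant, mol m^-2 s^-1.  Stored signed as
        tabulated (physical values are negative); the solver uses the
        magnitude as the dissolution flux.
    t_init : float
        Degradation onset time, days.
    r_initial : float
        Length of the Mg domain, m.
    l_electrolyte : float
        Length of the electrolyte domain, m (geometry bookkeeping only).
    dl_init : float
        Initial degradation-layer thickness, m.
    t_end : float
        Simulation horizon, days.
    n_t : int
        Number of time steps.
    n_x : int
        Spatial nodes (kept for grid-convention compatibility; the front
        tracking integrates the interface position directly).
    """

    epsilon: float = 0.05
    k_deg: float = -2.4321e-5
    t_init: float = 1.932
    r_initial: float = 0.2e-3
    l_electrolyte: float = 0.2e-3
    dl_init: float = 10e-9
    M_Mg: float = M_MG
    rho_Mg: float = RHO_MG
    t_end: float = 28.0
    n_t: int = 800
    n_x: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")
        if self.t_init < 0:
            raise ValueError("t_init must be >= 0")
        if self.r_initial <= 0:
            raise ValueError("r_initial must be > 0")
        if self.dl_init >= self.r_initial:
            raise ValueError("dl_init must be smaller than r_initial")
        if self.n_t < 2 or self.n_x < 2:
            raise ValueError("n_t and n_x must be >= 2")
        for name in ("epsilon", "k_deg", "t_init", "r_initial", "t_end"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def release_rate(
    t: float | np.ndarray, epsilon: float, k_deg: float, t_init: float
) -> float | np.ndarray:
    """Effective rate of Mg2+ release at the metal interface.

    ``eps * k_deg / (1 + exp(-(t - t_init)))`` with ``t``, ``t_init`` in
    days.  Returns the signed rate in the units of ``k_deg``
    (mol m^-2 s^-1); smooth and monotone towards the asymptote
    ``eps * k_deg``.
    """
    t = np.asarray(t, dtype=float)
    if not (0.0 < epsilon <= 1.0):
        raise ValueError("epsilon must be in (0, 1]")
    for name, val in (("k_deg", k_deg), ("t_init", t_init)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("t must be finite and >= 0")
    out = epsilon * k_deg / (1.0 + np.exp(-(t - t_init)))
    return float(out) if out.ndim == 0 else out


def simulate_mdd(config: QuasiOneDConfig) -> TimeSeriesOutput:
    """Track the metal interface and return MDD (um) on the time grid.

    The front velocity v_deg = (M_Mg/rho_Mg) * |release_rate| is integrated
    with the trapezoidal rule; the run is truncated (with a warning) if the
    Mg domain is consumed before ``t_end``.
    """
    t_days = np.linspace(0.0, config.t_end, config.n_t + 1)
    rate = release_rate(t_days, config.epsilon, config.k_deg, config.t_init)
    v = (config.M_Mg / config.rho_Mg) * np.abs(rate)  # m/s
    dt = (t_days[1] - t_days[0]) * DAY
    mdd = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    if mdd[-1] > config.r_initial:
        warnings.warn(
            "Mg domain consumed before t_end; MDD capped at r_initial",
            RuntimeWarning,
            stacklevel=2,
        )
        mdd = np.minimum(mdd, config.r_initial)
    return TimeSeriesOutput(times=t_days, values=mdd * 1e6, qoi_label="MDD_um")
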