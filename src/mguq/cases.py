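"""The three case studies: parameter spaces and desk-scale QoI bindings.

Testing ranges of the uncertain parameters (uniform on each interval,
signed exactly as tabulated; solvers act on magnitudes where a rate
magnitude is meant):

* model 1 (quasi-1D pure Mg): k_deg, t_init -> MDD;
* model 2 (precipitation): k_deg, t_init and six reaction constants
  k1..k6 (brucite, magnesite, nesquehonite, portlandite, calcite,
  hydroxyapatite) -> elemental wt% (Mg, O, P, C, Ca) of the layer;
* model 3 (diffusion volume loss): D_Mg -> VL.

QoI functions here run the simulators at reduced desk-scale resolutions
chosen so that halving the grid moves the headline QoIs by less than their
convergence tolerances while keeping a full adaptive-sampling study in the
minutes range on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from mguq.degradation_models import (
    DiffusionModelConfig,
    PrecipitationConfig,
    QuasiOneDConfig,
    simulate_mdd,
    simulate_precipitation,
    simulate_volume_loss,
)
from mguq.doe import ParameterSpace

#: (lower, upper, scale); kinetic constants are magnitude decades carrying
#: the sign of their calibrated values, sampled log-uniformly
MODEL1_RANGES = {
    "k_deg": (-1e-4, -1e-9, "log"),
    "t_init": (0.0, 3.0, "linear"),
}

MODEL2_RANGES = {
    "k_deg": (-1e-4, -1e-9, "log"),
    "t_init": (0.0, 3.0, "linear"),
    "brucite": (-1e-19, -1e-23, "log"),
    "magnesite": (-1e-5, -1e-12, "log"),
    "nesquehonite": (-1e-5, -1e-12, "log"),
    "portlandite": (-1e-1, -1e-12, "log"),
    "calcite": (-1e-19, -1e-25, "log"),
    "hydroxyapatite": (1e15, 1e20, "log"),
}

#: D_Mg in mm^2/s as tabulated; the solver works in SI (m^2/s = 1e-6 mm^2/s)
MODEL3_RANGES = {
    "D_Mg": (1e-12, 1e-4, "log"),
}

MM2_TO_M2 = 1e-6


def _ranges_to_bounds(ranges):
    return {k: (min(v[0], v[1]), max(v[0], v[1])) for k, v in ranges.items()}


#: plain [min, max] bounds per parameter (for containment checks)
MODEL1_BOUNDS = _ranges_to_bounds(MODEL1_RANGES)
MODEL2_BOUNDS = _ranges_to_bounds(MODEL2_RANGES)
MODEL3_BOUNDS = _ranges_to_bounds(MODEL3_RANGES)

#: wt% components reported as the model-2 QoI (H is tracked but not reported)
WT_ELEMENTS = ("Mg", "O", "P", "C", "Ca")


def _space(ranges) -> ParameterSpace:
    return ParameterSpace(
        [(k, v[0], v[1]) for k, v in ranges.items()],
        scales=[v[2] for v in ranges.values()],
    )


def model1_space() -> ParameterSpace:
    return _space(MODEL1_RANGES)


def model2_space() -> ParameterSpace:
    return _space(MODEL2_RANGES)


def model3_space() -> ParameterSpace:
    return _space(MODEL3_RANGES)


# --- desk-scale configurations -------------------------------------------


def model1_config(**overrides) -> QuasiOneDConfig:
    return QuasiOneDConfig(**{"n_t": 400, **overrides})


def model2_config(**overrides) -> PrecipitationConfig:
    return PrecipitationConfig(**{"n_t": 1200, "n_x": 30, **overrides})


def model3_config(**overrides) -> DiffusionModelConfig:
    return DiffusionModelConfig(**{"n_t": 112, "n_r": 34, "n_z": 40, **overrides})


# --- QoI bindings ----------------------------------------------------------


def model1_mdd_curve(x, days, config: QuasiOneDConfig | None = None) -> np.ndarray:
    """MDD (um) at the requested days for parameters x = (k_deg, t_init)."""
    k_deg, t_init = np.asarray(x, dtype=float).ravel()
    cfg = dataclasses.replace(config or model1_config(), k_deg=k_deg, t_init=t_init)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # interface consumption
        mdd = simulate_mdd(cfg)
    return np.atleast_1d(mdd.at(np.asarray(days, dtype=float)))


def model1_mdd28(x) -> float:
    """Scalar QoI of case 1: MDD at day 28."""
    return float(model1_mdd_curve(x, [28.0])[0])


def model2_wt(x, config: PrecipitationConfig | None = None) -> np.ndarray:
    """Day-28 wt% of (Mg, O, P, C, Ca) for x = (k_deg, t_init, k1..k6)."""
    x = np.asarray(x, dtype=float).ravel()
    names = list(MODEL2_RANGES)
    cfg = config or model2_config()
    cfg = dataclasses.replace(cfg, k_deg=x[0], t_init=x[1])
    cfg = cfg.with_rate_constants(dict(zip(names[2:], x[2:])))
    result = simulate_precipitation(cfg)
    wt = result.wt.values[-1]
    labels = result.wt.component_labels
    return np.array([wt[labels.index(e)] for e in WT_ELEMENTS])


def model2_wt_mg(x) -> float:
    """Scalar adaptive-sampling QoI of case 2: wt% of Mg at day 28."""
    return float(model2_wt(x)[0])


def model3_vl_curve(x, days, config: DiffusionModelConfig | None = None) -> np.ndarray:
    """VL (%) at the requested days for x = (D_Mg in mm^2/s,)."""
    d_mg = float(np.asarray(x, dtype=float).ravel()[0]) * MM2_TO_M2
    cfg = dataclasses.replace(config or model3_config(), D_Mg=d_mg)
    vl = simulate_volume_loss(cfg)
    return np.atleast_1d(vl.at(np.asarray(days, dtype=float)))


def model3_vl56(x) -> float:
    """Scalar QoI of case 3: VL at day 56."""
    return float(model3_vl_curve(x, [56.0])[0])


CASES = {
    1: {"space": model1_space, "qoi": model1_mdd28, "label": "MDD(28 d) / um"},
    2: {"space": model2_space, "qoi": model2_wt_mg, "label": "wt% Mg (28 d)"},
    3: {"space": model3_space, "qoi": model3_vl56, "label": "VL(56 d) / %"},
}
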