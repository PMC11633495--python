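"""Synthetic "experimental" calibration datasets with known ground truth.

The in-vitro measurements the degradation models are calibrated against
(micro-CT/weight-loss MDD curves, EDX elemental wt% of the degradation
layer, volume-loss curves of Mg-xGd) are not public; this module generates
stand-ins by running the simulators at known true parameters and adding
multiplicative Gaussian noise (degradation measurements scale with
magnitude, so relative noise is the default; 5% emulates typical
inter-specimen scatter).  Sampling cadence is weekly (days 7..28, plus 42
and 56 for volume loss), mimicking degradation-experiment practice.

Every dataset records its seed and true parameters, so calibration closes
the loop: in the noiseless limit the generating parameters are exactly
recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from mguq.degradation_models import (
    DiffusionModelConfig,
    PrecipitationConfig,
    QuasiOneDConfig,
    TimeSeriesOutput,
    simulate_mdd,
    simulate_precipitation,
    simulate_volume_loss,
)

#: Table-style parameter ranges of the three case studies (see cases module)
MDD_DAYS = (7.0, 14.0, 21.0, 28.0)
VL_DAYS = (7.0, 14.0, 21.0, 28.0, 42.0, 56.0)


@dataclass
class SyntheticDataset:
    """Noisy observations plus the ground truth that generated them."""

    true_params: dict[str, float]
    observations: TimeSeriesOutput
    noise_sd: float
    seed: int | None
    noise_model: str = "relative-gaussian"
    replicates: np.ndarray | None = None  # (n_rep, n_times[, n_components])

    def write(self, csv_path, sidecar_path=None) -> None:
        self.observations.to_csv(csv_path)
        if sidecar_path is not None:
            meta = {
                "true_params": self.true_params,
                "noise_model": self.noise_model,
                "noise_sd": self.noise_sd,
                "seed": self.seed,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _check_bounds(params: dict[str, float], bounds: dict[str, tuple[float, float]]) -> None:
    for name, val in params.items():
        lo, hi = bounds[name]
        if not (lo <= val <= hi):
            raise ValueError(f"{name}={val} outside the testing range [{lo}, {hi}]")


def _noisy(values: np.ndarray, noise_sd: float, rng, n_rep: int = 1,
           additive: bool = False) -> np.ndarray:
    z = rng.standard_normal((n_rep,) + values.shape)
    if additive:
        return values + noise_sd * z
    return values * (1.0 + noise_sd * z)


def make_mdd_dataset(
    k_deg: float,
    t_init: float,
    noise_sd: float = 0.05,
    seed: int | None = None,
    days=MDD_DAYS,
    n_replicates: int = 1,
    config: QuasiOneDConfig | None = None,
    additive: bool = False,
) -> SyntheticDataset:
    """Weekly MDD observations over 28 days from the quasi-1D model."""
    from mguq.cases import MODEL1_BOUNDS

    _check_bounds({"k_deg": k_deg, "t_init": t_init}, MODEL1_BOUNDS)
    if config is None:
        config = QuasiOneDConfig()
    config = dataclasses.replace(config, k_deg=k_deg, t_init=t_init)
    mdd = simulate_mdd(config)
    clean = mdd.at(np.asarray(days))
    rng = np.random.default_rng(seed)
    reps = np.maximum(_noisy(clean, noise_sd, rng, n_replicates, additive), 0.0)
    obs = TimeSeriesOutput(
        times=np.asarray(days, float), values=reps.mean(axis=0), qoi_label="MDD_um"
    )
    return SyntheticDataset(
        true_params={"k_deg": k_deg, "t_init": t_init},
        observations=obs,
        noise_sd=noise_sd,
        seed=seed,
        noise_model="additive-gaussian" if additive else "relative-gaussian",
        replicates=reps if n_replicates > 1 else None,
    )


def make_wt_dataset(
    rate_constants: dict[str, float],
    noise_sd: float = 0.05,
    seed: int | None = None,
    config: PrecipitationConfig | None = None,
    n_replicates: int = 1,
) -> SyntheticDataset:
    """Elemental wt% of the degradation layer at day 28 (EDX stand-in).

    ``rate_constants`` may contain ``k_deg``, ``t_init`` and the six
    reaction constants by precipitate name.  Noisy wt% rows are
    renormalised to sum to 100.
    """
    from mguq.cases import MODEL2_BOUNDS

    _check_bounds(rate_constants, MODEL2_BOUNDS)
    if config is None:
        config = PrecipitationConfig()
    kd = rate_constants.get("k_deg", config.k_deg)
    ti = rate_constants.get("t_init", config.t_init)
    config = dataclasses.replace(config, k_deg=kd, t_init=ti)
    config = config.with_rate_constants(
        {k: v for k, v in rate_constants.items() if k not in ("k_deg", "t_init")}
    )
    result = simulate_precipitation(config)
    clean = result.wt.values[-1]  # day-28 wt% vector (C, Ca, P, H, O, Mg)
    rng = np.random.default_rng(seed)
    reps = np.maximum(_noisy(clean, noise_sd, rng, n_replicates), 0.0)
    reps = reps / reps.sum(axis=-1, keepdims=True) * 100.0
    obs = TimeSeriesOutput(
        times=np.array([config.t_end]),
        values=reps.mean(axis=0)[None, :],
        qoi_label="wt_percent",
        component_labels=result.wt.component_labels,
    )
    return SyntheticDataset(
        true_params=dict(rate_constants),
        observations=obs,
        noise_sd=noise_sd,
        seed=seed,
        replicates=reps if n_replicates > 1 else None,
    )


def make_vl_dataset(
    D_Mg: float,
    alloy: str = "Mg-5Gd",
    noise_sd: float = 0.05,
    seed: int | None = None,
    days=VL_DAYS,
    config: DiffusionModelConfig | None = None,
    n_replicates: int = 1,
) -> SyntheticDataset:
    """Volume-loss observations over 56 days from the diffusion model.

    ``D_Mg`` is given in mm^2/s, matching the tabulated testing range; the
    solver works in SI internally.
    """
    from mguq.cases import MM2_TO_M2, MODEL3_BOUNDS

    _check_bounds({"D_Mg": D_Mg}, MODEL3_BOUNDS)
    if config is None:
        config = DiffusionModelConfig(alloy=alloy)
    config = dataclasses.replace(
        config, D_Mg=D_Mg * MM2_TO_M2, alloy=alloy, rho_alloy=None, c0_implant=None
    )
    vl = simulate_volume_loss(config)
    clean = vl.at(np.asarray(days))
    rng = np.random.default_rng(seed)
    reps = np.clip(_noisy(clean, noise_sd, rng, n_replicates), 0.0, 100.0)
    obs = TimeSeriesOutput(
        times=np.asarray(days, float), values=reps.mean(axis=0), qoi_label="VL_percent"
    )
    return SyntheticDataset(
        true_params={"D_Mg": D_Mg, "alloy": alloy},
        observations=obs,
        noise_sd=noise_sd,
        seed=seed,
        replicates=reps if n_replicates > 1 else None,
    )
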