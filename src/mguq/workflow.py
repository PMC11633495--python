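"""End-to-end workflow orchestration: DOE -> simulator -> surrogate -> UQ.

One master seed drives every stage through spawned substreams, so a run is
reproducible end to end; all artifacts (designs, responses, fitted
surrogates, Sobol indices, propagation summaries, calibration results) are
written as CSV/JSON and listed in a run manifest together with the
wall-time decomposition

    T_sim = T_BB^N + T_SM + T_opt + T_C + T_I

(black-box evaluations, surrogate training, parameter estimation;
communication and idle time are recorded as zero for an in-process run).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mguq import __version__
from mguq.cases import (
    CASES,
    MODEL2_RANGES,
    model1_mdd_curve,
    model1_space,
    model2_space,
    model2_wt,
    model3_space,
    model3_vl_curve,
)
from mguq.doe import adaptive_sample, min_one_shot_size, sample_one_shot
from mguq.surrogates import fit_kriging, fit_pce, fit_pck, fit_time_grid
from mguq.synthetic_data import make_mdd_dataset, make_vl_dataset
from mguq.uq_analysis import calibrate, propagate, sobol_from_pce, sobol_mc

_KNOWN_KEYS = {
    "model",
    "surrogate",
    "doe",
    "tasks",
    "theta",
    "budget",
    "n_initial",
    "sa_n",
    "propagate_n",
    "calibration_noise_sd",
}


@dataclass
class RunManifest:
    """Record of one workflow run: config echo, seed, timings, artifacts."""

    config: dict
    master_seed: int
    timings: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    version: str = __version__

    @property
    def t_sim(self) -> float:
        return float(sum(self.timings.values()))

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "master_seed": self.master_seed,
            "timings": self.timings,
            "T_sim": self.t_sim,
            "artifacts": self.artifacts,
            "stages_completed": self.stages_completed,
            "failed_stage": self.failed_stage,
            "version": self.version,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


_FITTERS = {
    "kriging": lambda X, Y, space, seed: fit_kriging(X, Y, space=space, seed=seed),
    "pce": lambda X, Y, space, seed: fit_pce(X, Y, space=space),
    "pck": lambda X, Y, space, seed: fit_pck(X, Y, space=space, seed=seed),
}

_SPACES = {1: model1_space, 2: model2_space, 3: model3_space}


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_workflow(config: dict, seed: int = 0, out_dir="mguq_run") -> RunManifest:
    """Execute the four-step UQ workflow described by ``config``.

    ``config`` keys: ``model`` (1|2|3), ``surrogate`` (kriging|pce|pck),
    ``doe`` ({"method": mc|lhs|sobol|halton|adaptive, "n": int}), ``tasks``
    (subset of ["sa", "propagate", "calibrate"]), plus optional tuning keys
    (theta, budget, n_initial, sa_n, propagate_n, calibration_noise_sd).
    Unknown keys are rejected.  Any stage failure is recorded in the
    manifest; artifacts produced before the failure are preserved.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    model_id = int(config.get("model", 1))
    if model_id not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    surrogate_name = str(config.get("surrogate", "kriging")).lower()
    if surrogate_name not in _FITTERS:
        raise ValueError("surrogate must be one of kriging, pce, pck")
    doe_cfg = dict(config.get("doe", {"method": "lhs"}))
    tasks = list(config.get("tasks", ["sa", "propagate"]))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, master_seed=seed)
    seeds = _spawn_seeds(seed, 6)
    s_doe, s_fit, s_sa, s_prop, s_cal, s_data = seeds

    space = _SPACES[model_id]()
    qoi = CASES[model_id]["qoi"]
    fitter = _FITTERS[surrogate_name]

    try:
        # --- step 1+2: design of experiments and black-box evaluations ----
        t0 = time.perf_counter()
        method = doe_cfg.get("method", "lhs").lower()
        if method == "adaptive":
            state, model = adaptive_sample(
                qoi,
                space,
                lambda X, Y: fitter(X, Y, space, s_fit),
                theta=float(config.get("theta", 1e-4)),
                budget=int(config.get("budget", 80)),
                n_initial=config.get("n_initial"),
                seed=s_doe,
            )
            X, Y = state.X, state.Y
            with open(out / "adaptive_history.json", "w") as fh:
                json.dump(
                    {
                        "eps_loo_history": state.eps_loo_history,
                        "n_initial": state.n_initial,
                        "stop_reason": state.stop_reason,
                        "theta": state.theta,
                        "budget": state.budget,
                    },
                    fh,
                    indent=2,
                )
            manifest.artifacts["adaptive_history"] = "adaptive_history.json"
        else:
            n = int(doe_cfg.get("n", min_one_shot_size(space.n_params)))
            X = sample_one_shot(space, n, method, seed=s_doe).points
            Y = np.array([qoi(x) for x in X])
            model = None
        manifest.timings["T_BB"] = time.perf_counter() - t0

        frame = pd.DataFrame(X, columns=space.names)
        frame.to_csv(out / "design.csv", index=False)
        pd.DataFrame({"qoi": Y}).to_csv(out / "responses.csv", index=False)
        manifest.artifacts["design"] = "design.csv"
        manifest.artifacts["responses"] = "responses.csv"
        manifest.stages_completed.append("doe")

        # --- step 3: surrogate construction --------------------------------
        t0 = time.perf_counter()
        if model is None:
            model = fitter(X, Y, space, s_fit)
        manifest.timings["T_SM"] = time.perf_counter() - t0
        if hasattr(model, "to_dict"):
            with open(out / "surrogate.json", "w") as fh:
                json.dump(model.to_dict(), fh)
            manifest.artifacts["surrogate"] = "surrogate.json"
        manifest.stages_completed.append("fit")

        # --- step 4: UQ tasks ----------------------------------------------
        t_opt = 0.0
        if "sa" in tasks:
            indices = _sensitivity(model, surrogate_name, space, config, s_sa)
            indices.to_frame().to_csv(out / "sobol_indices.csv", index=False)
            manifest.artifacts["sobol_indices"] = "sobol_indices.csv"
            manifest.stages_completed.append("sa")
        if "propagate" in tasks:
            prop = propagate(
                model, space, n=int(config.get("propagate_n", 500)), seed=s_prop
            )
            with open(out / "propagation.json", "w") as fh:
                json.dump(
                    {
                        "mean": prop.mean,
                        "variance": prop.variance,
                        "quantiles": {str(k): v for k, v in prop.quantiles.items()},
                        "n_samples": prop.n_samples,
                    },
                    fh,
                    indent=2,
                )
            manifest.artifacts["propagation"] = "propagation.json"
            manifest.stages_completed.append("propagate")
        if "calibrate" in tasks:
            t0 = time.perf_counter()
            result = _calibrate_against_synthetic(
                model_id, space, fitter, surrogate_name, config, s_cal, s_data, s_fit
            )
            t_opt = time.perf_counter() - t0
            with open(out / "calibration.json", "w") as fh:
                json.dump(
                    {
                        "params": result.params,
                        "objective": result.objective,
                        "surrogate": surrogate_name,
                        "trace": result.trace,
                    },
                    fh,
                    indent=2,
                )
            manifest.artifacts["calibration"] = "calibration.json"
            manifest.stages_completed.append("calibrate")
        manifest.timings["T_opt"] = t_opt
        manifest.timings["T_C"] = 0.0
        manifest.timings["T_I"] = 0.0
    except Exception as exc:
        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    manifest.artifacts["manifest"] = "manifest.json"
    return manifest


def _sensitivity(model, surrogate_name, space, config, seed):
    """Dispatch: analytic decomposition for PCE/PCK, pick-freeze MC otherwise."""
    if surrogate_name in ("pce", "pck"):
        return sobol_from_pce(model, param_names=space.names)
    return sobol_mc(model, space, n=int(config.get("sa_n", 1024)), seed=seed)


def _calibrate_against_synthetic(
    model_id, space, fitter, surrogate_name, config, s_cal, s_data, s_fit
):
    """Calibrate the surrogate against a synthetic dataset at the tabulated optimum."""
    noise = float(config.get("calibration_noise_sd", 0.05))
    if model_id == 1:
        data = make_mdd_dataset(-2.4321e-5, 1.932, noise_sd=noise, seed=s_data)
        days = data.observations.times
        X = sample_one_shot(space, 40, "lhs", seed=s_cal).points
        Yg = np.array([model1_mdd_curve(x, days) for x in X])
        sur = fit_time_grid(lambda A, B: fitter(A, B, space, s_fit), X, Yg, days)
        return calibrate(sur, data.observations, space, seed=s_cal)
    if model_id == 3:
        data = make_vl_dataset(6.05e-9, noise_sd=noise, seed=s_data)
        days = data.observations.times
        X = sample_one_shot(space, 25, "lhs", seed=s_cal).points
        Yg = np.array([model3_vl_curve(x, days) for x in X])
        sur = fit_time_grid(lambda A, B: fitter(A, B, space, s_fit), X, Yg, days)
        return calibrate(sur, data.observations, space, seed=s_cal)
    # model 2: per-element surrogates of the day-28 wt% vector
    from mguq.synthetic_data import make_wt_dataset

    truth = {name: MODEL2_RANGES[name][0] for name in MODEL2_RANGES}
    truth.update(
        {
            "k_deg": -2.4321e-5,
            "t_init": 1.932,
            "brucite": -9.0245e-21,
            "magnesite": -7.0332e-9,
            "nesquehonite": -7.0023e-10,
            "portlandite": -1.0798e-2,
            "calcite": -8.0037e-24,
            "hydroxyapatite": 9.001e16,
        }
    )
    data = make_wt_dataset(truth, noise_sd=noise, seed=s_data)
    X = sample_one_shot(space, 60, "lhs", seed=s_cal).points
    Yg = np.array([model2_wt(x) for x in X])  # (n, 5)
    labels = ["Mg", "O", "P", "C", "Ca"]
    obs_labels = data.observations.component_labels
    surrogates = {lab: fitter(X, Yg[:, j], space, s_fit) for j, lab in enumerate(labels)}
    # a single-element reference has zero range, so the five elements are
    # compared jointly as one QoI vector
    vec_obs = np.array(
        [data.observations.values[0][obs_labels.index(lab)] for lab in labels]
    )

    class _VecSurrogate:
        def predict(self, X_):
            return np.column_stack(
                [np.atleast_1d(surrogates[lab].predict(X_)) for lab in labels]
            ).ravel()

    return calibrate({"wt": _VecSurrogate()}, {"wt": vec_obs}, space, seed=s_cal)
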