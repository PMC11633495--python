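"""Time-series container shared by all simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeSeriesOutput:
    """A quantity of interest sampled on a strictly increasing time grid.

    Parameters
    ----------
    times : array of float
        Time points in days, strictly increasing.
    values : array
        QoI values; shape ``(n_times,)`` for scalar QoIs or
        ``(n_times, n_components)`` for vector QoIs such as per-element wt%.
    qoi_label : str
        What the values are (e.g. ``"MDD_um"``, ``"VL_percent"``).
    component_labels : list of str, optional
        Names of the columns when values is 2-D.
    """

    times: np.ndarray
    values: np.ndarray
    qoi_label: str = "qoi"
    component_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values length must match times")

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    def at(self, t_days: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the QoI at arbitrary times (days)."""
        t = np.atleast_1d(np.asarray(t_days, dtype=float))
        if self.values.ndim == 1:
            out = np.interp(t, self.times, self.values)
        else:
            out = np.column_stack(
                [np.interp(t, self.times, self.values[:, j]) for j in range(self.values.shape[1])]
            )
        return out[0] if np.isscalar(t_days) else out

    def to_frame(self) -> pd.DataFrame:
        if self.values.ndim == 1:
            return pd.DataFrame({"time_days": self.times, self.qoi_label: self.values})
        labels = self.component_labels or [
            f"{self.qoi_label}_{j}" for j in range(self.values.shape[1])
        ]
        frame = pd.DataFrame(self.values, columns=labels)
        frame.insert(0, "time_days", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
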