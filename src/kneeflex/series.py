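"""Timestamped angle series shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AngleSeries:
    """A knee or segment angle timeseries in degrees.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, monotone non-decreasing.
    angle : array of float
        Angle in degrees, one value per timestamp.
    """

    t: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.t.ndim != 1 or self.angle.ndim != 1:
            raise ValueError("t and angle must be one-dimensional")
        if self.t.shape != self.angle.shape:
            raise ValueError(
                f"t and angle lengths differ: {self.t.size} vs {self.angle.size}"
            )
        if self.t.size and np.any(np.diff(self.t) < 0):
            idx = int(np.argmax(np.diff(self.t) < 0)) + 1
            raise ValueError(f"timestamps decrease at sample {idx}")

    def __len__(self) -> int:
        return self.t.size

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= t <= t1."""
        return (self.t >= t0) & (self.t <= t1)

    def crop(self, t0: float, t1: float) -> "AngleSeries":
        m = self.window_mask(t0, t1)
        return AngleSeries(self.t[m], self.angle[m])

    def shifted(self, delta_deg: float) -> "AngleSeries":
        """Return a copy with a constant angle offset added."""
        return AngleSeries(self.t.copy(), self.angle + delta_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "angle_deg": self.angle})

    @classmethod
    def from_csv(cls, path) -> "AngleSeries":
        df = pd.read_csv(path)
        missing = {"t_s", "angle_deg"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(df["t_s"].to_numpy(), df["angle_deg"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
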