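"""Sensor-to-leg registration from the static box pose.

After every sensor re-application the mounting offsets are unknown, but the
knee angle only depends on their difference: with segment readings
``alpha_femur`` and ``alpha_tibia``,

    alpha_knee = alpha_femur - alpha_tibia - delta_knee

where ``delta_knee`` is estimated while the patient rests the leg on a rigid
box of known height and a goniometer supplies the true flexion ``alpha_pt``.
The offset is the mean raw relative angle over the still window minus
``alpha_pt``; applying it makes the window mean equal the goniometer reading
exactly, and any goniometer error propagates as a constant bias only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from kneeflex.series import AngleSeries


@dataclass
class GoniometerReading:
    """Clinician-measured knee flexion during the registration pose."""

    alpha_pt: float
    visit_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_pt <= 160.0:
            raise ValueError(f"implausible goniometer angle {self.alpha_pt} deg")


@dataclass
class RegistrationOffset:
    delta_knee: float
    window: tuple
    session_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_knee):
            raise ValueError("delta_knee must be finite")


def detect_box_pose_window(
    raw_relative: AngleSeries,
    min_duration: float = 2.0,
    stillness_sd: float = 0.5,
) -> tuple:
    """Find the longest still window of a raw relative-angle series.

    A rolling standard deviation over ``min_duration`` is computed; the
    longest contiguous run where it stays below ``stillness_sd`` is returned
    as a (t0, t1) window.  Raises if the series is shorter than
    ``min_duration`` or no qualifying window exists.
    """
    t = raw_relative.t
    if len(raw_relative) < 2 or t[-1] - t[0] < min_duration:
        raise ValueError("series shorter than the minimum stillness duration")
    dt = np.median(np.diff(t))
    win = max(2, int(round(min_duration / dt)))
    sd = pd.Series(raw_relative.angle).rolling(win).std()
    # rolling window i covers samples [i-win+1, i]; a below-threshold value
    # certifies stillness of that whole span
    ok = (sd < stillness_sd).to_numpy()
    if not ok.any():
        raise ValueError("no static pose found (rolling SD never below threshold)")
    # longest run of certified windows
    padded = np.concatenate([[False], ok, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]  # ends exclusive
    best = int(np.argmax(ends - starts))
    i0 = max(0, int(starts[best]) - win + 1)
    i1 = int(ends[best]) - 1
    return (float(t[i0]), float(t[i1]))


def compute_offset(
    raw_relative: AngleSeries,
    window: tuple,
    gonio: GoniometerReading,
    session_id: str = "",
) -> RegistrationOffset:
    """Registration offset: mean raw relative angle over the window minus the
    goniometer reading."""
    t0, t1 = float(window[0]), float(window[1])
    if t1 < t0:
        raise ValueError("window end precedes start")
    vals = raw_relative.angle[raw_relative.window_mask(t0, t1)]
    if vals.size == 0:
        raise ValueError(f"window [{t0}, {t1}] contains no samples")
    if np.isnan(vals).any():
        raise ValueError("NaN angles inside the registration window")
    return RegistrationOffset(float(vals.mean()) - gonio.alpha_pt, (t0, t1), session_id)


def apply_offset(raw_relative: AngleSeries, offset: RegistrationOffset) -> AngleSeries:
    """Knee flexion series: raw relative angle minus the registration offset."""
    return raw_relative.shifted(-offset.delta_knee)
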