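"""Resampling and covariance-lag synchronization of sensor and video series.

Both series are brought onto a common uniform grid (the video frame rate,
60 fps by default) by cubic-spline interpolation, then synchronized by the
integer sample offset that maximizes the covariance between the two series.
Each candidate lag is scored by the normalized covariance (Pearson
correlation) of the two series over that lag's overlap.  The normalization by
both windows' standard deviations is what makes the argmax well behaved on
exercise recordings, which are strongly nonstationary (still registration
pose, ramp, steady cycles): an un-normalized covariance can be inflated by a
candidate window that happens to catch more high-variance motion, whereas the
correlation is bounded by 1 with equality exactly at a perfect linear match,
so the true lag wins on noise-free data over any overlap.  A periodically
shifted candidate of a steady cyclic exercise is rejected by the
registration-pose segment it fails to match; only a perfectly periodic signal
scores an exact tie, in which case the tie breaks toward the smallest
absolute lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from kneeflex.series import AngleSeries


@dataclass
class AlignedPair:
    """Time-aligned sensor and video flexion on a common uniform grid."""

    t: np.ndarray
    sensor: np.ndarray
    video: np.ndarray
    lag_applied: int = 0
    rate: float = 60.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sensor = np.asarray(self.sensor, dtype=float)
        self.video = np.asarray(self.video, dtype=float)
        if not (self.t.size == self.sensor.size == self.video.size):
            raise ValueError("t, sensor and video must have equal lengths")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            # 2e-6 s slack admits timestamps round-tripped through text files
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=2e-6):
                raise ValueError("t must be strictly increasing and uniform")

    @property
    def bias(self) -> np.ndarray:
        """Signed deviation sensor - video, degrees."""
        return self.sensor - self.video

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "sensor_deg": self.sensor, "video_deg": self.video})


def resample_to_rate(series: AngleSeries, rate: float) -> AngleSeries:
    """Cubic-spline resampling onto the uniform grid at ``rate`` Hz spanning
    the series' interior (no extrapolation)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(series) < 4:
        raise ValueError("need at least 4 samples for cubic-spline resampling")
    t = series.t
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or decreasing timestamps")
    i0 = int(np.ceil(round(t[0] * rate, 9)))
    i1 = int(np.floor(round(t[-1] * rate, 9)))
    if i1 < i0:
        raise ValueError("series too short for the target grid")
    grid = np.arange(i0, i1 + 1) / rate
    if grid.size == t.size and np.allclose(grid, t, atol=1e-12):
        return AngleSeries(grid, series.angle.copy())
    return AngleSeries(grid, CubicSpline(t, series.angle)(grid))


def _lag_score(a: np.ndarray, b: np.ndarray, shift: int, min_len: int) -> float:
    """Normalized covariance of a[i] vs b[i + shift] over their overlap;
    NaN when the overlap is too short or either window is constant."""
    lo = max(0, -shift)
    hi = min(a.size, b.size - shift)
    if hi - lo < min_len:
        return float("nan")
    xa = a[lo:hi] - a[lo:hi].mean()
    xb = b[lo + shift: hi + shift] - b[lo + shift: hi + shift].mean()
    na2 = float(np.dot(xa, xa))
    nb2 = float(np.dot(xb, xb))
    if na2 == 0.0 or nb2 == 0.0:
        return float("nan")
    return float(np.dot(xa, xb)) / math.sqrt(na2 * nb2)


def _best_lag(a: np.ndarray, b: np.ndarray, offset: int,
              max_lag: int, min_len: int) -> int:
    """Argmax over lags in [-max_lag, max_lag] of the per-overlap normalized
    covariance of a[i] vs b[i + offset + lag].

    Visits lags in order of increasing |lag| and requires a relative
    improvement of 1e-9, so the smallest-|lag| candidate wins symmetric ties
    (perfectly periodic signals) down to floating-point jitter.
    """
    best_lag, best_score = 0, -np.inf
    for mag in range(0, int(max_lag) + 1):
        for lag in ((mag,) if mag == 0 else (mag, -mag)):
            c = _lag_score(a, b, offset + lag, min_len)
            if math.isnan(c):
                continue
            if best_score == -np.inf or c > best_score + 1e-9 * abs(best_score) + 1e-15:
                best_lag, best_score = lag, c
    if best_score == -np.inf:
        raise ValueError("no candidate lag leaves the minimum overlap")
    return best_lag


def find_lag_by_covariance(
    a: AngleSeries,
    b: AngleSeries,
    max_lag: int,
    min_overlap_s: float = 2.0,
) -> int:
    """Integer lag in [-max_lag, +max_lag] whose pairing a[i] vs b[i + lag]
    has the highest normalized covariance over its overlap.

    Both series must be uniform at the same rate; the lag is index-based.
    Ties break toward the smallest |lag| (and toward the positive lag at
    equal magnitude).  Raises for constant (zero-variance) inputs, for which
    the lag is undefined.
    """
    rate_a = 1.0 / np.median(np.diff(a.t))
    rate_b = 1.0 / np.median(np.diff(b.t))
    if not np.isclose(rate_a, rate_b, rtol=1e-6):
        raise ValueError(f"sampling rates differ: {rate_a:.6g} vs {rate_b:.6g} Hz")
    if np.ptp(a.angle) == 0.0 or np.ptp(b.angle) == 0.0:
        raise ValueError("constant series: covariance lag is undefined")
    min_len = max(2, int(round(min_overlap_s * rate_a)))
    return _best_lag(a.angle, b.angle, 0, int(max_lag), min_len)


def align_pair(
    sensor: AngleSeries,
    video: AngleSeries,
    rate: float = 60.0,
    max_lag: int = 600,
    min_overlap_s: float = 2.0,
) -> AlignedPair:
    """Resample both series to ``rate``, synchronize by covariance lag, and
    trim to the common overlap.

    The returned ``lag_applied`` is the number of grid samples the video
    series was advanced (positive lag = video recorded the same motion later).
    """
    s = resample_to_rate(sensor, rate)
    v = resample_to_rate(video, rate)
    # place both on the absolute grid index so different start times are honest
    i0s = int(round(s.t[0] * rate))
    i0v = int(round(v.t[0] * rate))
    lag = _find_lag_absolute(s, v, i0s, i0v, max_lag, min_overlap_s, rate)
    # sensor index i pairs with video absolute index i0s + i + lag
    j = np.arange(s.t.size) + i0s + lag - i0v
    ok = (j >= 0) & (j < v.t.size)
    if ok.sum() < max(2, int(round(min_overlap_s * rate))):
        raise ValueError("overlap after synchronization is shorter than the minimum")
    return AlignedPair(s.t[ok], s.angle[ok], v.angle[j[ok]], lag_applied=lag, rate=rate)


def _find_lag_absolute(s, v, i0s, i0v, max_lag, min_overlap_s, rate) -> int:
    """Lag search with both series indexed on the shared absolute grid."""
    if np.ptp(s.angle) == 0.0 or np.ptp(v.angle) == 0.0:
        raise ValueError("constant series: covariance lag is undefined")
    min_len = max(2, int(round(min_overlap_s * rate)))
    offset = i0s - i0v  # sensor sample i sits at video-local index i + offset
    return _best_lag(s.angle, v.angle, offset, int(max_lag), min_len)
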