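"""Agreement statistics between sensor and video knee angles.

Covers the accuracy surface of the validation analysis: signed bias
(sensor - video) summarized in 5-degree flexion bins (mean, mean-absolute,
sample SD, central-95% range), an overall row averaging across bins, ordinary
least-squares agreement between the two measurements, repeatability summaries
of the registration procedure, and a continuous piecewise-linear model of
bias versus flexion angle (three segments, two freely fitted breakpoints)
used to correct the sensor readings.

The piecewise fit uses the standard formulation: for fixed breakpoints the
model is linear in its coefficients (intercept, slope, and one hinge term per
breakpoint) and is solved by least squares; the breakpoints themselves are
found by a seeded global search (differential evolution) over the interior of
the angle range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from kneeflex.align import AlignedPair

ROM_MIN_DEG = 0.0
ROM_MAX_DEG = 110.0  # bins outside this span are reported but excluded from overall rows


@dataclass
class BinnedBiasTable:
    """Per-bin bias statistics; ``table`` has one row per half-open bin
    [left, right) with columns n, mean_bias, mae, sd, p95_range, in_range."""

    table: pd.DataFrame
    bin_width: float
    bin_by: str

    @property
    def n_total(self) -> int:
        return int(self.table["n"].sum())


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


@dataclass
class PiecewiseLinearModel:
    """Continuous piecewise-linear bias model.

    ``breakpoints`` are the interior segment boundaries (strictly increasing)
    and ``segments`` the per-segment (intercept, slope) pairs, each segment
    reported as its own line y = intercept + slope * x.  Prediction outside
    the fitted range extrapolates with the nearest segment.
    """

    breakpoints: np.ndarray
    segments: list
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.segments) != self.breakpoints.size + 1:
            raise ValueError("need one more segment than breakpoints")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        seg = np.searchsorted(self.breakpoints, x, side="right")
        inter = np.array([s[0] for s in self.segments])
        slope = np.array([s[1] for s in self.segments])
        return inter[seg] + slope[seg] * x


@dataclass
class RepeatabilityReport:
    """Per-patient and pooled repeatability statistics (degrees)."""

    per_patient: pd.DataFrame
    pooled_mean: float
    pooled_max: float = float("nan")
    pooled_sd: float = float("nan")
    reading_min: float = float("nan")
    reading_max: float = float("nan")
    flagged: list = field(default_factory=list)


def binned_bias_table(
    pair: AlignedPair,
    bin_width: float = 5.0,
    bin_by: str = "sensor",
) -> BinnedBiasTable:
    """Bias statistics in half-open flexion bins [k*w, (k+1)*w).

    Samples are binned by the sensor (default) or video angle.  Per bin:
    count, mean bias, mean absolute bias, sample SD (n-1), and the width of
    the central 95% of bias values.  Empty bins inside the covered span get
    n = 0 and NaN statistics.
    """
    if bin_by not in ("sensor", "video"):
        raise ValueError("bin_by must be 'sensor' or 'video'")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    key = pair.sensor if bin_by == "sensor" else pair.video
    if key.size == 0:
        raise ValueError("empty aligned pair")
    bias = pair.bias
    k0 = int(np.floor(key.min() / bin_width))
    k1 = int(np.floor(key.max() / bin_width))
    rows = []
    for k in range(k0, k1 + 1):
        left, right = k * bin_width, (k + 1) * bin_width
        sel = bias[(key >= left) & (key < right)]
        if sel.size:
            lo, hi = np.percentile(sel, [2.5, 97.5])
            rows.append((left, right, sel.size, sel.mean(), np.abs(sel).mean(),
                         sel.std(ddof=1) if sel.size > 1 else 0.0, hi - lo))
        else:
            rows.append((left, right, 0, np.nan, np.nan, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["bin_left", "bin_right", "n", "mean_bias",
                                     "mae", "sd", "p95_range"])
    df["in_range"] = (df["bin_left"] >= ROM_MIN_DEG) & (df["bin_right"] <= ROM_MAX_DEG)
    return BinnedBiasTable(df, bin_width, bin_by)


def overall_summary(table) -> tuple:
    """Unweighted across-bin means of per-bin mean bias and per-bin MAE.

    Accepts a :class:`BinnedBiasTable` (non-empty in-range bins only) or any
    DataFrame/sequence of rows with ``mean_bias`` and ``mae`` columns.
    """
    if isinstance(table, BinnedBiasTable):
        df = table.table
        df = df[df["in_range"] & (df["n"] > 0)]
    else:
        df = pd.DataFrame(table)
    if len(df) == 0 or df["mean_bias"].isna().all():
        raise ValueError("no non-empty bins to summarize")
    return float(df["mean_bias"].mean()), float(df["mae"].mean())


def fit_linear_agreement(pair: AlignedPair) -> LinearFit:
    """OLS of sensor on video: sensor = intercept + slope * video."""
    if pair.t.size < 3:
        raise ValueError("need at least 3 samples for a linear fit")
    if np.ptp(pair.video) == 0.0:
        raise ValueError("constant predictor: video series has no spread")
    res = stats.linregress(pair.video, pair.sensor)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue ** 2))


def _hinge_design(x: np.ndarray, bps: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in bps:
        cols.append(np.maximum(0.0, x - b))
    return np.column_stack(cols)


def _pwl_ssr(bps_sorted: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple:
    A = _hinge_design(x, bps_sorted)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r), coef


def fit_piecewise_bias(
    points,
    n_segments: int = 3,
    seed: int = 0,
    bias=None,
) -> PiecewiseLinearModel:
    """Least-squares continuous piecewise-linear fit of bias on flexion angle
    with free interior breakpoints.

    ``points`` is a sequence of (angle, bias) pairs, or the angle array when
    ``bias`` is given separately.  Breakpoints are optimized by seeded
    differential evolution over the interior of the angle range (the inner
    problem, with breakpoints fixed, is solved in closed form).
    """
    if bias is None:
        pts = np.asarray(list(points), dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    else:
        x = np.asarray(points, dtype=float)
        y = np.asarray(bias, dtype=float)
    if n_segments < 1:
        raise ValueError("need at least one segment")
    if x.size < 2 * n_segments + 2:
        raise ValueError(f"need at least {2 * n_segments + 2} points for {n_segments} segments")
    if np.unique(x).size < 2 * n_segments:
        raise ValueError("degenerate angle spread for the requested segment count")

    sst = float(np.sum((y - y.mean()) ** 2))
    n_bp = n_segments - 1
    x_lo, x_hi = float(x.min()), float(x.max())
    margin = 0.02 * (x_hi - x_lo)
    # a minimum separation keeps every segment identifiable; collapsed
    # breakpoints otherwise fit a sliver segment with wild coefficients
    min_gap = 0.02 * (x_hi - x_lo)

    if n_bp == 0:
        ssr, coef = _pwl_ssr(np.empty(0), x, y)
        bps = np.empty(0)
    else:
        def objective(b):
            b = np.sort(b)
            if n_bp > 1 and np.min(np.diff(b)) < min_gap:
                # finite penalty keeps the polishing step differentiable
                return 1e6 * (sst + 1.0)
            return _pwl_ssr(b, x, y)[0]

        bounds = [(x_lo + margin, x_hi - margin)] * n_bp
        res = optimize.differential_evolution(
            objective, bounds, seed=seed, popsize=20, maxiter=200,
            tol=1e-10, polish=True,
        )
        bps = np.sort(res.x)
        ssr, coef = _pwl_ssr(bps, x, y)

    # convert hinge coefficients to per-segment (intercept, slope) lines
    segments = []
    inter, slope = float(coef[0]), float(coef[1])
    segments.append((inter, slope))
    for j, b in enumerate(bps):
        slope += float(coef[2 + j])
        inter -= float(coef[2 + j]) * float(b)
        segments.append((inter, slope))
    r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    # collapsed breakpoints can come back unordered-equal after sorting; nudge
    for i in range(1, bps.size):
        if bps[i] <= bps[i - 1]:
            bps[i] = np.nextafter(bps[i - 1], np.inf)
    return PiecewiseLinearModel(bps, segments, max(0.0, min(1.0, r2)))


def apply_piecewise_correction(pair: AlignedPair, model: PiecewiseLinearModel) -> AlignedPair:
    """Correct the sensor angles by the model's predicted bias.

    corrected sensor = sensor - predicted_bias(sensor); the video series is
    untouched.  Downstream binning of the result re-bins by the corrected
    sensor angle, which is what makes a corrected bias table self-consistent.
    """
    corrected = pair.sensor - model.predict(pair.sensor)
    return AlignedPair(pair.t, corrected, pair.video, pair.lag_applied, pair.rate)


def goniometer_repeatability(readings) -> RepeatabilityReport:
    """Between-visit repeatability of the goniometer reading.

    ``readings`` maps patient -> (visit1, visit2) in degrees.  Reports the
    per-patient absolute difference, their pooled mean and sample SD, and the
    min/max over all individual readings.
    """
    rows = []
    all_vals = []
    for patient, pair in readings.items():
        if pair is None or len(pair) != 2 or any(v is None for v in pair):
            raise ValueError(f"patient {patient}: both visits are required")
        v1, v2 = float(pair[0]), float(pair[1])
        rows.append((patient, v1, v2, abs(v1 - v2)))
        all_vals += [v1, v2]
    if not rows:
        raise ValueError("no patients with paired visits")
    df = pd.DataFrame(rows, columns=["patient", "visit1", "visit2", "abs_diff"])
    diffs = df["abs_diff"].to_numpy()
    return RepeatabilityReport(
        per_patient=df,
        pooled_mean=float(diffs.mean()),
        pooled_max=float(diffs.max()),
        pooled_sd=float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        reading_min=float(min(all_vals)),
        reading_max=float(max(all_vals)),
    )


def pose_repeatability(offsets) -> RepeatabilityReport:
    """Within-session repeatability of the registration pose.

    ``offsets`` maps patient -> list of sessions, each a sequence of repeated
    offset angles (deg).  Within each session the mean is removed; the
    per-patient statistics are the mean and max of the absolute demeaned
    values over all the patient's repeats, and the pooled mean weights each
    patient by repeat count.  Single-repeat sessions contribute zero spread
    and are flagged.
    """
    rows = []
    flagged = []
    for patient, sessions in offsets.items():
        if sessions and np.isscalar(sessions[0]):
            sessions = [sessions]
        resid = []
        for si, sess in enumerate(sessions):
            vals = np.asarray(sess, dtype=float)
            if vals.size == 0:
                raise ValueError(f"patient {patient}: empty session")
            if vals.size == 1:
                flagged.append((patient, si))
            resid.append(vals - vals.mean())
        resid = np.abs(np.concatenate(resid))
        rows.append((patient, resid.size, resid.mean(), resid.max()))
    if not rows:
        raise ValueError("no repeated offsets")
    df = pd.DataFrame(rows, columns=["patient", "n", "mean_abs", "max_abs"])
    pooled_mean, pooled_max = pool_repeatability(df["mean_abs"], df["n"], df["max_abs"])
    return RepeatabilityReport(df, pooled_mean, pooled_max, flagged=flagged)


def pool_repeatability(per_patient_mean, counts, per_patient_max=None) -> tuple:
    """Repeat-count-weighted pooled mean (and max) of per-patient statistics."""
    m = np.asarray(per_patient_mean, dtype=float)
    n = np.asarray(counts, dtype=float)
    if m.shape != n.shape or m.size == 0:
        raise ValueError("per-patient means and counts must be equal-length, non-empty")
    pooled_mean = float(np.sum(m * n) / np.sum(n))
    pooled_max = float(np.max(per_patient_max)) if per_patient_max is not None else float("nan")
    return pooled_mean, pooled_max
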