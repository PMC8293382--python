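"""Published reference measurements from the clinical validation study.

These are the printed summary tables of the eight-patient validation of the
two-sensor system: paired goniometer readings from the two clinic visits,
per-patient repeatability of the registration pose, bias statistics of
sensor versus video flexion in 5-degree bins (before and after piecewise
correction), and the parameters of the fitted piecewise bias model.  They
serve as fixed inputs for reproducing the study's aggregate statistics; the
raw per-sample recordings were never released.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Goniometer knee flexion on the box (deg), initial and final clinic visit.
GONIOMETER_VISITS = {
    1: (60, 62),
    2: (65, 63),
    3: (60, 62),
    4: (58, 50),
    5: (59, 56),
    6: (60, 56),
    7: (74, 74),
    8: (60, 60),
}

# Per-patient repeatability of the registration-pose offset angle (deg).
POSE_REPEATABILITY = pd.DataFrame(
    {
        "patient": [1, 2, 3, 4, 5, 6, 7, 8],
        "n": [5, 5, 5, 5, 5, 5, 5, 4],
        "mean_abs": [0.6, 2.0, 2.3, 0.7, 3.2, 0.5, 2.9, 0.3],
        "max_abs": [1.4, 3.5, 5.2, 1.4, 5.5, 0.7, 4.8, 0.5],
    }
)

# Bias (sensor - video, deg) in 5-degree flexion bins, uncorrected and after
# the piecewise-linear correction: mean, mean-absolute and SD per bin.
_BIN_ROWS = [
    # left, mean, mae, sd, corr_mean, corr_mae, corr_sd
    (0, 3.98, 4.95, 1.61, 0.74, 1.29, 1.61),
    (5, 2.45, 1.78, 1.45, 0.12, 1.27, 1.57),
    (10, 2.51, 2.80, 2.65, 1.90, 2.40, 2.64),
    (15, 0.84, 2.17, 3.01, 0.67, 2.28, 3.03),
    (20, 0.34, 2.43, 3.23, -0.06, 2.51, 3.22),
    (25, 1.12, 2.91, 3.30, 0.54, 2.61, 3.31),
    (30, 0.48, 2.61, 2.87, 0.03, 2.21, 2.87),
    (35, 0.21, 2.58, 2.97, 0.02, 2.23, 2.97),
    (40, 0.00, 2.55, 2.99, 0.07, 2.24, 3.00),
    (45, -0.16, 2.58, 3.08, 0.17, 2.24, 3.08),
    (50, -0.21, 2.48, 3.09, 0.39, 2.29, 3.09),
    (55, -0.31, 2.20, 2.71, 0.54, 2.00, 2.71),
    (60, -0.42, 2.13, 2.97, 0.68, 2.21, 2.97),
    (65, -0.61, 1.90, 2.68, 0.76, 2.03, 2.68),
    (70, -1.44, 2.11, 2.55, 0.18, 1.92, 2.55),
    (75, -2.03, 2.52, 2.76, -0.14, 2.15, 2.76),
    (80, -3.75, 3.74, 2.74, -1.58, 2.64, 2.72),
    (85, -3.20, 3.14, 2.72, -0.83, 2.35, 2.74),
    (90, -2.49, 2.49, 2.99, 0.14, 2.29, 2.97),
    (95, -2.73, 2.61, 3.39, 0.19, 2.75, 3.41),
    (100, -2.07, 2.28, 3.79, 1.12, 3.25, 3.81),
    (105, -3.95, 3.12, 4.10, -0.55, 3.29, 4.08),
]

BINNED_BIAS = pd.DataFrame(
    _BIN_ROWS,
    columns=["bin_left", "mean_bias", "mae", "sd", "corr_mean_bias", "corr_mae", "corr_sd"],
)
BINNED_BIAS["bin_right"] = BINNED_BIAS["bin_left"] + 5.0
BINNED_BIAS["bin_center"] = BINNED_BIAS["bin_left"] + 2.5

# Fitted piecewise bias model: breakpoints at 15 and 47 deg, each segment a
# line (intercept, slope) in bias-vs-flexion space.  The printed coefficients
# are rounded and therefore not exactly continuous at the breakpoints.
PIECEWISE_BREAKPOINTS = np.array([15.0, 47.0])
PIECEWISE_SEGMENTS = [(4.43, -0.23), (0.51, -0.01), (2.71, -0.06)]

# Per-exercise-session bias summaries (mean, mean-absolute, SD in degrees)
# with time-aligned duration in seconds, as printed per logging session.
SESSION_SUMMARIES = pd.DataFrame(
    [
        (3, 2, "long_arc_quad", 57.17, 1.80, 1.26, 1.91),
        (3, 2, "long_arc_quad", 42.48, 0.41, 1.14, 1.91),
        (3, 2, "standing_knee_bend", 133.37, 0.16, 2.57, 3.01),
        (3, 2, "standing_knee_bend", 72.96, -0.99, 1.93, 2.40),
        (3, 2, "standing_knee_bend", 96.13, 1.58, 2.40, 2.87),
        (3, 2, "standing_knee_bend", 92.78, -1.43, 1.68, 2.29),
        (4, 2, "long_arc_quad", 117.15, 1.56, 1.86, 2.75),
        (4, 2, "standing_knee_bend", 80.73, -3.55, 3.46, 4.15),
        (4, 2, "standing_knee_bend", 64.36, -3.50, 2.96, 3.62),
        (4, 2, "standing_knee_bend", 87.10, -3.04, 3.98, 4.65),
        (4, 2, "standing_knee_bend", 106.99, -4.73, 2.96, 3.70),
        (4, 1, "standing_knee_bend", 64.18, -1.98, 3.22, 3.85),
        (5, 2, "long_arc_quad", 108.17, 1.49, 1.39, 1.87),
        (5, 2, "standing_knee_bend", 111.28, -0.97, 3.40, 3.87),
        (5, 1, "standing_knee_bend", 29.25, -0.87, 2.40, 3.22),
        (5, 1, "standing_knee_bend", 132.82, -0.79, 1.82, 2.27),
        (6, 2, "standing_knee_bend", 150.40, -0.48, 4.41, 4.91),
        (6, 2, "standing_knee_bend", 174.92, -0.37, 3.33, 4.07),
        (6, 2, "standing_knee_bend", 185.19, -0.05, 2.29, 2.84),
        (7, 1, "standing_knee_bend", 157.39, 0.75, 2.35, 2.79),
    ],
    columns=["patient", "visit", "exercise", "duration_s", "mean_bias", "mae", "sd"],
)
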