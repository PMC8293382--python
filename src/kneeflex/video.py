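"""Knee flexion from 2D hip/knee/ankle keypoints.

The per-frame knee angle is the internal angle between the hip-to-knee and
ankle-to-knee vectors; flexion is reported as 180 deg minus that internal
angle so that 0 deg means a straight leg.  The angle is invariant to image
translation, rotation and uniform scaling, so the camera pose does not enter.
A constant residual offset (keypoint placement bias) is removed by anchoring
the series to the same goniometer reading used for sensor registration —
because sensor and video share the anchor, a goniometer error cancels in
their difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from kneeflex.registration import GoniometerReading
from kneeflex.series import AngleSeries

logger = logging.getLogger(__name__)

# BODY-25 keypoint indices, used when reading raw OpenPose output
_BODY25 = {
    "right": {"hip": 9, "knee": 10, "ankle": 11},
    "left": {"hip": 12, "knee": 13, "ankle": 14},
}


@dataclass
class KeypointFrame:
    frame_index: int
    hip: tuple  # (x, y, confidence)
    knee: tuple
    ankle: tuple


def _frame_from_triplets(idx, hip, knee, ankle) -> KeypointFrame:
    for name, p in (("hip", hip), ("knee", knee), ("ankle", ankle)):
        if not 0.0 <= p[2] <= 1.0:
            raise ValueError(f"frame {idx}: {name} confidence {p[2]} outside [0, 1]")
        if p[2] > 0 and not (np.isfinite(p[0]) and np.isfinite(p[1])):
            raise ValueError(f"frame {idx}: non-finite {name} coordinates")
    return KeypointFrame(int(idx), tuple(hip), tuple(knee), tuple(ankle))


def _parse_json(data: dict, side: str):
    if "frames" in data:
        for fr in data["frames"]:
            yield _frame_from_triplets(fr["frame"], fr["hip"], fr["knee"], fr["ankle"])
        return
    if "people_frames" in data:  # raw BODY-25 style: per frame, people with flat arrays
        idxs = _BODY25[side]
        for fr in data["people_frames"]:
            people = fr.get("people", [])
            if not people:
                continue
            kp = people[0]["pose_keypoints_2d"]
            joints = {
                name: kp[3 * j: 3 * j + 3] for name, j in idxs.items()
            }
            yield _frame_from_triplets(fr["frame"], joints["hip"], joints["knee"], joints["ankle"])
        return
    raise ValueError("unrecognised keypoint JSON layout")


def read_keypoints(path, fmt: str = "auto", confidence_min: float = 0.3, side: str = "right"):
    """Read keypoint frames from JSON or flat CSV, dropping low-confidence ones.

    Frames where any joint confidence is below ``confidence_min`` are dropped
    (and logged); original frame indices are preserved on the retained frames.
    Raises if the file is malformed, empty, or every frame is dropped.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        data = json.loads(path.read_text())
        frames = list(_parse_json(data, side))
    elif fmt == "csv":
        df = pd.read_csv(path)
        needed = {"frame", "hip_x", "hip_y", "hip_c", "knee_x", "knee_y", "knee_c",
                  "ankle_x", "ankle_y", "ankle_c"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing keypoint columns {sorted(missing)}")
        frames = [
            _frame_from_triplets(
                r.frame,
                (r.hip_x, r.hip_y, r.hip_c),
                (r.knee_x, r.knee_y, r.knee_c),
                (r.ankle_x, r.ankle_y, r.ankle_c),
            )
            for r in df.itertuples(index=False)
        ]
    else:
        raise ValueError(f"unknown keypoint format {fmt!r}")
    if not frames:
        raise ValueError(f"{path}: no keypoint frames")
    kept = [f for f in frames if min(f.hip[2], f.knee[2], f.ankle[2]) >= confidence_min]
    n_drop = len(frames) - len(kept)
    if n_drop:
        logger.info("%s: dropped %d/%d frames below confidence %.2f",
                    path.name, n_drop, len(frames), confidence_min)
    if not kept:
        raise ValueError(f"{path}: all {len(frames)} frames below confidence {confidence_min}")
    return kept


def frames_from_dataframe(df: pd.DataFrame, confidence_min: float = 0.3):
    """Keypoint frames from an in-memory flat table (same dialect as the CSV),
    dropping frames with any joint confidence below ``confidence_min``."""
    frames = [
        _frame_from_triplets(
            r.frame,
            (r.hip_x, r.hip_y, r.hip_c),
            (r.knee_x, r.knee_y, r.knee_c),
            (r.ankle_x, r.ankle_y, r.ankle_c),
        )
        for r in df.itertuples(index=False)
    ]
    kept = [f for f in frames if min(f.hip[2], f.knee[2], f.ankle[2]) >= confidence_min]
    if not kept:
        raise ValueError("all keypoint frames below the confidence threshold")
    return kept


def dropped_fraction(path, confidence_min: float = 0.3, **kw) -> float:
    """QC metric: fraction of frames rejected by the confidence filter."""
    all_frames = read_keypoints(path, confidence_min=0.0, **kw)
    kept = [f for f in all_frames if min(f.hip[2], f.knee[2], f.ankle[2]) >= confidence_min]
    return 1.0 - len(kept) / len(all_frames)


def knee_angle_from_keypoints(frame: KeypointFrame, *, internal: bool = False) -> float:
    """Knee flexion (deg) of one frame.

    Flexion is 180 deg minus the internal angle between (hip - knee) and
    (ankle - knee); pass ``internal=True`` for the raw internal angle.
    """
    hip = np.asarray(frame.hip[:2], dtype=float)
    knee = np.asarray(frame.knee[:2], dtype=float)
    ankle = np.asarray(frame.ankle[:2], dtype=float)
    u = hip - knee
    v = ankle - knee
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError(f"frame {frame.frame_index}: coincident keypoints, angle undefined")
    # atan2 of |cross| and dot is numerically stable near 0 and 180 deg
    cross = u[0] * v[1] - u[1] * v[0]
    internal_deg = np.degrees(np.arctan2(abs(cross), float(np.dot(u, v))))
    return float(internal_deg if internal else 180.0 - internal_deg)


def video_angle_series(frames, frame_rate: float = 60.0) -> AngleSeries:
    """Flexion series for a sequence of keypoint frames (t = frame / rate)."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    t = np.array([f.frame_index for f in frames], dtype=float) / frame_rate
    ang = np.array([knee_angle_from_keypoints(f) for f in frames])
    return AngleSeries(t, ang)


def correct_video_offset(series: AngleSeries, window: tuple, gonio: GoniometerReading) -> AngleSeries:
    """Anchor the video series to the goniometer: subtract (window mean -
    alpha_pt) so the window mean equals the goniometer reading exactly."""
    vals = series.angle[series.window_mask(float(window[0]), float(window[1]))]
    if vals.size == 0:
        raise ValueError("correction window does not overlap the video series")
    return series.shifted(gonio.alpha_pt - float(vals.mean()))
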