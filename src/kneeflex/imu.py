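"""Orientation fusion of 6-DOF inertial streams and sagittal-angle extraction.

Each sensor node carries a 3-axis gyroscope (deg/s) and a 3-axis
accelerometer (g).  Orientation is estimated with the gradient-descent
complementary filter of Madgwick: the quaternion rate from gyro integration
is corrected by a step along the gradient of the gravity-alignment error,
scaled by the gain ``beta``.  Only the sagittal inclination of the sensor's
long (body-z) axis is consumed downstream, so the magnetometer-free variant
suffices and heading drift is irrelevant.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` and map body to world.
* World frame: z up, x forward; the sagittal plane is x-z and segment
  rotation is about the world y axis.
* At identity orientation the segment is vertical (0 deg inclination);
  forward rotation of the distal end increases the angle.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

IMU_COLUMNS = ["t_s", "gx_dps", "gy_dps", "gz_dps", "ax_g", "ay_g", "az_g"]

_D2R = math.pi / 180.0
_R2D = 180.0 / math.pi


def read_imu_csv(path) -> pd.DataFrame:
    """Read a per-sensor inertial stream (t_s, gx..gz in deg/s, ax..az in g)."""
    df = pd.read_csv(path)
    missing = set(IMU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing IMU columns {sorted(missing)}")
    return df[IMU_COLUMNS]


def quat_from_accel(accel) -> np.ndarray:
    """Tilt-from-gravity initial orientation.

    Returns the quaternion of the rotation that takes the measured specific
    force direction onto the world up axis, i.e. the minimal-rotation (zero
    yaw) orientation consistent with a static accelerometer sample.
    """
    a = np.asarray(accel, dtype=float)
    n = np.linalg.norm(a)
    if n == 0.0 or not np.isfinite(n):
        raise ValueError("cannot initialise orientation from a zero accelerometer sample")
    a = a / n
    ez = np.array([0.0, 0.0, 1.0])
    axis = np.cross(a, ez)
    s = np.linalg.norm(axis)
    c = float(np.dot(a, ez))
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # upside-down: 180 deg about x (any horizontal axis works)
        return np.array([0.0, 1.0, 0.0, 0.0])
    axis = axis / s
    half = 0.5 * math.atan2(s, c)
    return np.array([math.cos(half), *(math.sin(half) * axis)])


def madgwick_step(q: np.ndarray, gyro_dps, accel_g, dt: float, beta: float = 0.1) -> np.ndarray:
    """One filter update: gyro quaternion integration plus a normalized
    gradient-descent correction toward the measured gravity direction.

    A zero-norm accelerometer sample disables the corrective term for that
    step (pure gyro integration).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    q0, q1, q2, q3 = (float(v) for v in q)
    gx, gy, gz = (float(v) * _D2R for v in gyro_dps)
    ax, ay, az = (float(v) for v in accel_g)

    # gyro term via the quaternion exponential: exact for a constant rate
    # over the step, so beta = 0 reduces to true dead-reckoning
    wnorm = math.sqrt(gx * gx + gy * gy + gz * gz)
    if wnorm > 0.0:
        half = 0.5 * wnorm * dt
        c, s = math.cos(half), math.sin(half) / wnorm
        dq0, dq1, dq2, dq3 = c, s * gx, s * gy, s * gz
        q0, q1, q2, q3 = (
            q0 * dq0 - q1 * dq1 - q2 * dq2 - q3 * dq3,
            q0 * dq1 + q1 * dq0 + q2 * dq3 - q3 * dq2,
            q0 * dq2 - q1 * dq3 + q2 * dq0 + q3 * dq1,
            q0 * dq3 + q1 * dq2 - q2 * dq1 + q3 * dq0,
        )

    anorm = math.sqrt(ax * ax + ay * ay + az * az)
    if beta > 0.0 and anorm > 0.0:
        ax, ay, az = ax / anorm, ay / anorm, az / anorm
        # objective: predicted gravity (body frame) minus measurement
        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
        g0 = -2.0 * q2 * f1 + 2.0 * q1 * f2
        g1 = 2.0 * q3 * f1 + 2.0 * q0 * f2 - 4.0 * q1 * f3
        g2 = -2.0 * q0 * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
        g3 = 2.0 * q1 * f1 + 2.0 * q2 * f2
        gn = math.sqrt(g0 * g0 + g1 * g1 + g2 * g2 + g3 * g3)
        # saturated step: normalized for large misalignment, proportional once
        # the gradient norm drops below 1 — a strictly normalized step has a
        # beta*dt limit cycle around equilibrium on clean data
        scale = beta * dt / max(gn, 1.0)
        q0 -= scale * g0
        q1 -= scale * g1
        q2 -= scale * g2
        q3 -= scale * g3

    n = math.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    return np.array([q0 / n, q1 / n, q2 / n, q3 / n])


def fuse_stream(stream: pd.DataFrame, beta: float = 0.1, init: str = "accel_tilt"):
    """Fuse an inertial stream into an orientation series.

    Parameters
    ----------
    stream : DataFrame
        Columns ``t_s, gx_dps, gy_dps, gz_dps, ax_g, ay_g, az_g``.
    beta : float
        Filter gain; ``beta=0`` reduces to gyro dead-reckoning.
    init : {"accel_tilt", "identity"}
        Initial orientation: tilt-from-gravity from the first accelerometer
        sample, or the identity quaternion.

    Returns
    -------
    (t, quats) : (ndarray (n,), ndarray (n, 4))
    """
    if len(stream) < 2:
        raise ValueError("need at least 2 samples to fuse a stream")
    t = stream["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValueError(f"non-monotone timestamps at sample {int(bad[0]) + 1}")
    gyro = stream[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float)
    accel = stream[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if not (np.all(np.isfinite(gyro)) and np.all(np.isfinite(accel))):
        raise ValueError("non-finite values in inertial stream")

    if init == "accel_tilt":
        q = quat_from_accel(accel[0])
    elif init == "identity":
        q = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown init {init!r}; use 'accel_tilt' or 'identity'")

    quats = np.empty((len(t), 4))
    quats[0] = q
    # trapezoidal gyro over each interval halves the integration phase error
    gmid = (0.5 * (gyro[1:] + gyro[:-1])).tolist()
    alist = accel.tolist()
    for i in range(1, len(t)):
        q = madgwick_step(q, gmid[i - 1], alist[i], float(dt[i - 1]), beta)
        quats[i] = q
    return t, quats


def sagittal_angle(q: np.ndarray, *, flag_degenerate: bool = True) -> float:
    """Sagittal inclination (deg) of the body z axis for one orientation.

    The body-fixed long axis is rotated to the world frame and projected onto
    the x-z plane; the angle is measured from vertical, positive forward.
    Orientations whose long axis is nearly normal to the sagittal plane are
    rejected (the projection is then meaningless).
    """
    q0, q1, q2, q3 = (float(v) for v in q)
    vx = 2.0 * (q1 * q3 + q0 * q2)
    vy = 2.0 * (q2 * q3 - q0 * q1)
    vz = 1.0 - 2.0 * (q1 * q1 + q2 * q2)
    if flag_degenerate and vx * vx + vz * vz < 1e-6:
        raise ValueError(
            "gimbal-degenerate orientation: segment axis is normal to the sagittal plane"
        )
    return math.atan2(vx, vz) * _R2D


def segment_angle_series(t: np.ndarray, quats: np.ndarray):
    """Sagittal angle series (deg) for a fused orientation series, unwrapped.

    Returns an :class:`~kneeflex.series.AngleSeries`-compatible pair via the
    shared container so the trace is continuous across the +-180 deg seam.
    """
    from kneeflex.series import AngleSeries

    q = np.asarray(quats, dtype=float)
    vx = 2.0 * (q[:, 1] * q[:, 3] + q[:, 0] * q[:, 2])
    vz = 1.0 - 2.0 * (q[:, 1] ** 2 + q[:, 2] ** 2)
    raw = np.arctan2(vx, vz)
    return AngleSeries(np.asarray(t, dtype=float), np.degrees(np.unwrap(raw)))


def relative_angle(thigh: "np.ndarray | object", shank) -> "object":
    """Raw relative segment angle (thigh minus shank) on the thigh's grid.

    Both arguments are angle series; the shank is linearly interpolated onto
    the thigh timestamps when the grids differ.
    """
    from kneeflex.series import AngleSeries

    if not np.array_equal(thigh.t, shank.t):
        shank_on_thigh = np.interp(thigh.t, shank.t, shank.angle)
    else:
        shank_on_thigh = shank.angle
    return AngleSeries(thigh.t, thigh.angle - shank_on_thigh)
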