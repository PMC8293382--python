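"""Synthetic exercise sessions for the two-sensor knee pipeline.

Emulates a rehabilitation session as recorded by the real system: a patient
rests the operated leg on a rigid box for a few seconds (the registration
pose), then performs a cyclic flexion exercise (standing knee bends or long
arc quads) while two misaligned inertial sensors record at 50 Hz and a
sagittal camera records hip/knee/ankle keypoints at 60 fps.  All kinematics
are planar (hinge knee, laterally mounted sensors), gravity is the only
specific force modelled by default, and every random draw is governed by a
single seed.

The decomposition of the knee angle into segment angles is exercise
specific: standing knee bends share the motion between a forward-tilting
thigh and a backward-swinging shank, while long arc quads keep the thigh
fixed near horizontal (seated) and swing the shank only.  Only the
difference (the knee angle) matters downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kneeflex.series import AngleSeries

BOX_POSE_DURATION_S = 5.0  # stationary registration pose prepended to each session
RAMP_DURATION_S = 2.0  # smooth transition from the pose into the exercise
SWAY_FREQ_HZ = 0.3  # slow postural sway while holding the pose

# (thigh share of knee motion, thigh baseline inclination in deg)
_EXERCISE_DECOMPOSITION = {
    "standing_knee_bend": (0.35, 0.0),
    "long_arc_quad": (0.0, 85.0),
    "custom": (0.5, 0.0),
}

KEYPOINT_COLUMNS = [
    "frame",
    "hip_x", "hip_y", "hip_c",
    "knee_x", "knee_y", "knee_c",
    "ankle_x", "ankle_y", "ankle_c",
]


@dataclass
class MotionProfile:
    """Cyclic flexion exercise: angle oscillates between flexion_min and
    flexion_max with the given period, for the given duration."""

    exercise: str = "standing_knee_bend"
    flexion_min: float = 10.0
    flexion_max: float = 90.0
    period: float = 4.0
    duration: float = 60.0
    waveform: str = "sinusoid"

    def __post_init__(self) -> None:
        if self.exercise not in _EXERCISE_DECOMPOSITION:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if self.waveform not in ("sinusoid", "smoothed_triangle"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.flexion_min > self.flexion_max:
            raise ValueError("flexion_min must not exceed flexion_max")
        if self.period <= 0 or self.duration <= 0:
            raise ValueError("period and duration must be positive")


@dataclass
class SensorMountSpec:
    """Sensor mounting misalignments and inertial error model."""

    delta_f: float = 0.0  # thigh sensor-to-mechanical-axis offset, deg
    delta_t: float = 0.0  # shank offset, deg
    gyro_noise_sd: float = 0.0  # deg/s
    gyro_bias: float = 0.0  # deg/s, on the rotation (body-y) axis
    accel_noise_sd: float = 0.0  # g
    sample_rate: float = 50.0  # Hz

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.gyro_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CameraSpec:
    """Sagittal-plane camera and keypoint error model (image y points down)."""

    frame_rate: float = 60.0
    pixel_noise_sd: float = 0.0
    thigh_length: float = 300.0  # hip-to-knee, pixels
    shank_length: float = 300.0  # knee-to-ankle, pixels
    hip_origin: tuple = (960.0, 300.0)
    dropout_prob: float = 0.0
    angle_bias_deg: float = 0.0  # systematic keypoint placement error

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.thigh_length <= 0 or self.shank_length <= 0:
            raise ValueError("segment lengths must be positive")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be non-negative")


@dataclass
class SyntheticScenario:
    """Everything needed to simulate one session reproducibly."""

    profile: MotionProfile = field(default_factory=MotionProfile)
    mounts: SensorMountSpec = field(default_factory=SensorMountSpec)
    camera: CameraSpec = field(default_factory=CameraSpec)
    time_lag: float = 0.0  # video delayed relative to sensors, s
    box_pose_angle: float = 60.0  # true knee flexion on the box, deg
    goniometer_error: float = 0.0  # alpha_PT minus true box-pose angle, deg
    sway_deg: float = 0.15  # postural sway amplitude while on the box
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """True planar kinematics on a uniform grid (angles in deg, rates deg/s)."""

    time: np.ndarray
    alpha_knee_true: np.ndarray
    alpha_femur_true: np.ndarray
    alpha_tibia_true: np.ndarray
    femur_rate: np.ndarray | None = None
    tibia_rate: np.ndarray | None = None


@dataclass
class SimulatedSession:
    imu_thigh: pd.DataFrame
    imu_shank: pd.DataFrame
    keypoints: pd.DataFrame
    manifest: dict
    truth: GroundTruth


def _triangle_coeffs(n_harmonics: int = 4):
    """Fourier coefficients of a [0, 1] triangle wave, truncated and rescaled
    so the smoothed waveform attains exactly 0 (at phase 0) and 1 (phase 0.5)."""
    ns = np.arange(1, 2 * n_harmonics, 2)  # odd harmonics 1, 3, 5, 7
    c = 4.0 / (np.pi ** 2 * ns ** 2)
    return ns, c / (2.0 * c.sum())


def _waveform_unit(x: np.ndarray, waveform: str):
    """Normalized cycle in [0, 1] and its derivative w.r.t. phase x (cycles).

    x = 0 is the cycle start at the minimum with zero rate.
    """
    x = np.asarray(x, dtype=float)
    if waveform == "sinusoid":
        u = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
        du = np.pi * np.sin(2.0 * np.pi * x)
        return u, du
    ns, c = _triangle_coeffs()
    arg = 2.0 * np.pi * np.outer(x.ravel(), ns)
    u = 0.5 - (np.cos(arg) * c).sum(axis=1)
    du = (np.sin(arg) * (c * 2.0 * np.pi * ns)).sum(axis=1)
    return u.reshape(x.shape), du.reshape(x.shape)


def _knee_exercise(t: np.ndarray, profile: MotionProfile):
    """Knee angle (deg) and rate (deg/s) of the exercise at times t >= 0."""
    amp = profile.flexion_max - profile.flexion_min
    u, du = _waveform_unit(t / profile.period, profile.waveform)
    return profile.flexion_min + amp * u, amp * du / profile.period


def generate_profile(profile: MotionProfile, rate: float, *, allow_constant: bool = False) -> GroundTruth:
    """Sample the exercise ground truth on a uniform grid at ``rate`` Hz.

    Rejects non-positive rates, a duration shorter than one period, and a
    constant (flexion_min == flexion_max) profile unless ``allow_constant``.
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    if profile.duration < profile.period:
        raise ValueError("duration must cover at least one period")
    if profile.flexion_min == profile.flexion_max and not allow_constant:
        raise ValueError("degenerate constant profile; pass allow_constant=True to keep it")
    n = int(round(profile.duration * rate))
    t = np.arange(n) / rate
    knee, rate_dps = _knee_exercise(t, profile)
    share, base = _EXERCISE_DECOMPOSITION[profile.exercise]
    femur = base + share * knee
    tibia = base - (1.0 - share) * knee
    return GroundTruth(t, knee, femur, tibia, share * rate_dps, -(1.0 - share) * rate_dps)


class _SessionTrajectory:
    """Closed-form knee trajectory of a full session: box pose, ramp into the
    exercise, then the cyclic exercise.  Evaluable at arbitrary times, which
    is what lets the camera stream be delayed by a fractional lag exactly."""

    def __init__(self, scn: SyntheticScenario):
        self.scn = scn
        self.t_ramp = BOX_POSE_DURATION_S
        self.t_ex = BOX_POSE_DURATION_S + RAMP_DURATION_S
        self.t_end = self.t_ex + scn.profile.duration
        self.k_start, _ = _knee_exercise(np.zeros(1), scn.profile)
        self.k_start = float(self.k_start[0])

    def knee(self, t: np.ndarray):
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, self.t_end)
        k = np.empty_like(tc)
        kd = np.empty_like(tc)
        scn = self.scn

        box = tc < self.t_ramp
        w = 2.0 * np.pi * SWAY_FREQ_HZ
        k[box] = scn.box_pose_angle + scn.sway_deg * np.sin(w * tc[box])
        kd[box] = scn.sway_deg * w * np.cos(w * tc[box])

        ramp = (tc >= self.t_ramp) & (tc < self.t_ex)
        x = (tc[ramp] - self.t_ramp) / RAMP_DURATION_S
        a0 = scn.box_pose_angle + scn.sway_deg * np.sin(w * self.t_ramp)
        k[ramp] = a0 + (self.k_start - a0) * 0.5 * (1.0 - np.cos(np.pi * x))
        kd[ramp] = (self.k_start - a0) * 0.5 * np.pi * np.sin(np.pi * x) / RAMP_DURATION_S

        ex = tc >= self.t_ex
        k[ex], kd[ex] = _knee_exercise(tc[ex] - self.t_ex, scn.profile)
        kd[t != tc] = 0.0  # clamped ends are held still
        return k, kd

    def segments(self, t: np.ndarray):
        """Femur/tibia angles and rates consistent with the knee trajectory."""
        share, base = _EXERCISE_DECOMPOSITION[self.scn.profile.exercise]
        k, kd = self.knee(t)
        femur = base + share * k
        tibia = base - (1.0 - share) * k
        return femur, tibia, share * kd, -(1.0 - share) * kd


def _gravity_in_sensor_frame(angle_deg: np.ndarray) -> np.ndarray:
    """Accelerometer reading (g) of a sensor pitched by ``angle`` about y."""
    th = np.radians(angle_deg)
    return np.column_stack([-np.sin(th), np.zeros_like(th), np.cos(th)])


def _imu_stream(t, angle_deg, rate_dps, mounts: SensorMountSpec, rng) -> pd.DataFrame:
    gyro = np.zeros((t.size, 3))
    gyro[:, 1] = rate_dps + mounts.gyro_bias
    gyro += rng.normal(0.0, mounts.gyro_noise_sd, size=gyro.shape)
    accel = _gravity_in_sensor_frame(angle_deg)
    accel += rng.normal(0.0, mounts.accel_noise_sd, size=accel.shape)
    return pd.DataFrame(
        {
            "t_s": t,
            "gx_dps": gyro[:, 0],
            "gy_dps": gyro[:, 1],
            "gz_dps": gyro[:, 2],
            "ax_g": accel[:, 0],
            "ay_g": accel[:, 1],
            "az_g": accel[:, 2],
        }
    )


def keypoints_from_angles(femur_deg, tibia_deg, camera: CameraSpec):
    """Hip/knee/ankle pixel positions for segment inclinations (y-down image).

    The hip is fixed at ``hip_origin``; the thigh and shank hang from it with
    the given inclinations from vertical (positive forward = +x).
    """
    hx, hy = camera.hip_origin
    fr = np.radians(np.asarray(femur_deg, dtype=float))
    tr = np.radians(np.asarray(tibia_deg, dtype=float))
    knee_x = hx + camera.thigh_length * np.sin(fr)
    knee_y = hy + camera.thigh_length * np.cos(fr)
    ankle_x = knee_x + camera.shank_length * np.sin(tr)
    ankle_y = knee_y + camera.shank_length * np.cos(tr)
    hip = np.column_stack([np.full_like(knee_x, hx), np.full_like(knee_y, hy)])
    return hip, np.column_stack([knee_x, knee_y]), np.column_stack([ankle_x, ankle_y])


def simulate_session(scn: SyntheticScenario) -> SimulatedSession:
    """Simulate one full session: two inertial streams, a keypoint stream and
    the session manifest, all driven by ``scn.rng_seed``.

    The video stream is delayed by ``scn.time_lag``: frame i (video time
    i/fps) shows the pose the leg had at sensor time i/fps - time_lag.
    """
    traj = _SessionTrajectory(scn)
    rng = np.random.default_rng(scn.rng_seed)

    fs = scn.mounts.sample_rate
    t_imu = np.arange(int(round(traj.t_end * fs))) / fs
    femur, tibia, femur_rate, tibia_rate = traj.segments(t_imu)
    imu_thigh = _imu_stream(t_imu, femur + scn.mounts.delta_f, femur_rate, scn.mounts, rng)
    imu_shank = _imu_stream(t_imu, tibia + scn.mounts.delta_t, tibia_rate, scn.mounts, rng)

    fps = scn.camera.frame_rate
    n_frames = int(round(traj.t_end * fps))
    frames = np.arange(n_frames)
    femur_v, tibia_v, _, _ = traj.segments(frames / fps - scn.time_lag)
    b = scn.camera.angle_bias_deg
    hip, knee, ankle = keypoints_from_angles(femur_v + 0.5 * b, tibia_v - 0.5 * b, scn.camera)
    pts = np.stack([hip, knee, ankle], axis=1)  # (n, 3 joints, 2)
    pts += rng.normal(0.0, scn.camera.pixel_noise_sd, size=pts.shape)
    conf = rng.uniform(0.55, 1.0, size=(n_frames, 3))
    dropped = rng.random(n_frames) < scn.camera.dropout_prob
    conf[dropped] = rng.uniform(0.0, 0.25, size=(int(dropped.sum()), 3))
    keypoints = pd.DataFrame(
        {
            "frame": frames,
            "hip_x": pts[:, 0, 0], "hip_y": pts[:, 0, 1], "hip_c": conf[:, 0],
            "knee_x": pts[:, 1, 0], "knee_y": pts[:, 1, 1], "knee_c": conf[:, 1],
            "ankle_x": pts[:, 2, 0], "ankle_y": pts[:, 2, 1], "ankle_c": conf[:, 2],
        }
    )

    knee_true, _ = traj.knee(t_imu)
    truth = GroundTruth(t_imu, knee_true, femur, tibia, femur_rate, tibia_rate)
    manifest = {
        "alpha_pt_deg": float(scn.box_pose_angle + scn.goniometer_error),
        "box_pose_window": [0.0, BOX_POSE_DURATION_S],
        "frame_rate_hz": float(fps),
        "sample_rate_hz": float(fs),
        "side": "right",
        "true_params": {
            "delta_f_deg": float(scn.mounts.delta_f),
            "delta_t_deg": float(scn.mounts.delta_t),
            "delta_knee_deg": float(scn.mounts.delta_f - scn.mounts.delta_t),
            "time_lag_s": float(scn.time_lag),
            "box_pose_angle_deg": float(scn.box_pose_angle),
            "goniometer_error_deg": float(scn.goniometer_error),
            "rng_seed": int(scn.rng_seed),
        },
    }
    return SimulatedSession(imu_thigh, imu_shank, keypoints, manifest, truth)


def truth_series(session: SimulatedSession) -> AngleSeries:
    """Ground-truth knee angle of a simulated session as an AngleSeries."""
    return AngleSeries(session.truth.time, session.truth.alpha_knee_true)


def write_fixtures(session: SimulatedSession, out_dir) -> dict:
    """Write a session to disk: two IMU CSVs, keypoints as both flat CSV and
    JSON, and the YAML manifest.  Floats are written at fixed precision so a
    read-back round trip reproduces the written values exactly."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "imu_thigh": out / "imu_thigh.csv",
            "imu_shank": out / "imu_shank.csv",
            "keypoints_csv": out / "keypoints.csv",
            "keypoints_json": out / "keypoints.json",
            "manifest": out / "manifest.yaml",
        }
        session.imu_thigh.to_csv(paths["imu_thigh"], index=False, float_format="%.6f")
        session.imu_shank.to_csv(paths["imu_shank"], index=False, float_format="%.6f")
        session.keypoints.to_csv(paths["keypoints_csv"], index=False, float_format="%.3f")
        frames = [
            {
                "frame": int(r.frame),
                "hip": [round(r.hip_x, 3), round(r.hip_y, 3), round(r.hip_c, 3)],
                "knee": [round(r.knee_x, 3), round(r.knee_y, 3), round(r.knee_c, 3)],
                "ankle": [round(r.ankle_x, 3), round(r.ankle_y, 3), round(r.ankle_c, 3)],
            }
            for r in session.keypoints.itertuples(index=False)
        ]
        paths["keypoints_json"].write_text(json.dumps({"frames": frames}, indent=1))
        paths["manifest"].write_text(yaml.safe_dump(session.manifest, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {out}: {exc}") from exc
    return paths
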