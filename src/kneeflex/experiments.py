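"""Self-contained validation experiments built on the synthetic generator.

These functions reproduce, on simulated data, the bench and study procedures
that characterize the system: the static mechanical-hinge accuracy of the
orientation filter, and the full simulate -> fuse -> register -> video ->
align -> bias chain on one synthetic session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from kneeflex import align, bias, imu, registration, synth, video
from kneeflex.series import AngleSeries


def static_hinge_max_error(
    seed: int = 0,
    n_angles: int = 12,
    n_seeds: int = 5,
    duration_s: float = 10.0,
    rate_hz: float = 50.0,
    settle_s: float = 2.0,
    beta: float = 0.1,
) -> float:
    """Static accuracy of the fusion stage on a noise-free mechanical hinge.

    Two simulated sensors sit on a rigid hinge held at ``n_angles`` fixed
    hinge angles spanning 0-110 deg; per trial the thigh-side tilt is drawn
    at random (the hinge angle is exact).  Accelerometers read pure gravity,
    gyros read zero.  Both streams are fused for ``duration_s`` at
    ``rate_hz``; after discarding the first ``settle_s`` the registered hinge
    angle (thigh minus shank sagittal angle) is compared with truth.  Returns
    the maximum absolute error over all angles and seeds, in degrees.
    """
    rng = np.random.default_rng(seed)
    hinge_angles = np.linspace(0.0, 110.0, n_angles)
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    worst = 0.0
    for _ in range(n_seeds):
        for hinge in hinge_angles:
            thigh_tilt = float(rng.uniform(-10.0, 100.0))
            shank_tilt = thigh_tilt - hinge
            err = _static_pair_error(t, thigh_tilt, shank_tilt, hinge, beta, settle_s)
            worst = max(worst, err)
    return worst


def _static_stream(t: np.ndarray, tilt_deg: float) -> pd.DataFrame:
    th = np.radians(tilt_deg)
    n = t.size
    return pd.DataFrame(
        {
            "t_s": t,
            "gx_dps": np.zeros(n), "gy_dps": np.zeros(n), "gz_dps": np.zeros(n),
            "ax_g": np.full(n, -np.sin(th)),
            "ay_g": np.zeros(n),
            "az_g": np.full(n, np.cos(th)),
        }
    )


def _static_pair_error(t, thigh_tilt, shank_tilt, hinge, beta, settle_s) -> float:
    tt, qt = imu.fuse_stream(_static_stream(t, thigh_tilt), beta=beta)
    ts, qs = imu.fuse_stream(_static_stream(t, shank_tilt), beta=beta)
    femur = imu.segment_angle_series(tt, qt)
    tibia = imu.segment_angle_series(ts, qs)
    rel = imu.relative_angle(femur, tibia)
    keep = rel.t >= settle_s
    return float(np.max(np.abs(rel.angle[keep] - hinge)))


def run_synthetic_session(scn: synth.SyntheticScenario, *,
                          beta: float = 0.1,
                          rate_hz: float = 60.0,
                          max_lag_s: float = 10.0,
                          bin_width: float = 5.0,
                          n_segments: int = 3,
                          pwl_seed: int = 0,
                          fit_piecewise: bool = True) -> dict:
    """End-to-end analysis of one simulated session.

    Returns a dict with the registered sensor series, corrected video series,
    aligned pair, binned bias table, linear agreement fit and (optionally)
    the piecewise bias model with its corrected table.
    """
    session = synth.simulate_session(scn)
    gonio = registration.GoniometerReading(session.manifest["alpha_pt_deg"])
    window = tuple(session.manifest["box_pose_window"])

    tt, qt = imu.fuse_stream(session.imu_thigh, beta=beta)
    ts, qs = imu.fuse_stream(session.imu_shank, beta=beta)
    raw_rel = imu.relative_angle(imu.segment_angle_series(tt, qt),
                                 imu.segment_angle_series(ts, qs))
    offset = registration.compute_offset(raw_rel, window, gonio)
    knee_sensor = registration.apply_offset(raw_rel, offset)

    frames = video.frames_from_dataframe(session.keypoints, confidence_min=0.3)
    knee_video = video.video_angle_series(frames, scn.camera.frame_rate)

    # synchronize first (covariance is blind to constant offsets), then anchor
    # the video series to the goniometer over the box window in sensor time
    pair = align.align_pair(knee_sensor, knee_video, rate=rate_hz,
                            max_lag=int(round(max_lag_s * rate_hz)))
    vid_corr = video.correct_video_offset(AngleSeries(pair.t, pair.video), window, gonio)
    pair = align.AlignedPair(pair.t, pair.sensor, vid_corr.angle,
                             pair.lag_applied, pair.rate)
    table = bias.binned_bias_table(pair, bin_width=bin_width)
    fit = bias.fit_linear_agreement(pair)
    out = {
        "session": session,
        "offset": offset,
        "sensor": knee_sensor,
        "video": vid_corr,
        "pair": pair,
        "table": table,
        "linear_fit": fit,
    }
    if fit_piecewise:
        model = bias.fit_piecewise_bias(
            np.column_stack([pair.sensor, pair.bias]), n_segments=n_segments, seed=pwl_seed
        )
        corrected = bias.apply_piecewise_correction(pair, model)
        out["pwl_model"] = model
        out["corrected_pair"] = corrected
        out["corrected_table"] = bias.binned_bias_table(corrected, bin_width=bin_width)
    return out
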