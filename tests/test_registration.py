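"""Box-pose registration: window detection, offset estimation, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kneeflex as kf
from kneeflex import registration as reg
from kneeflex.experiments import run_synthetic_session
from kneeflex.series import AngleSeries
from tests.conftest import make_scenario


def _flat_then_motion(flat_s=5.0, rate=50.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(20 * rate)) / rate
    ang = np.where(t < flat_s, 60.0, 60.0 + 30.0 * np.sin(2 * np.pi * (t - flat_s) / 3.0))
    return AngleSeries(t, ang + rng.normal(0, noise_sd, t.size))


class TestDetectBoxPoseWindow:
    def test_flat_prefix_found(self):
        t0, t1 = reg.detect_box_pose_window(_flat_then_motion())
        assert t0 == pytest.approx(0.0, abs=0.1)
        assert 4.0 <= t1 <= 5.5

    def test_fully_dynamic_series_fails(self):
        t = np.arange(500) / 50.0
        s = AngleSeries(t, 40 + 40 * np.sin(2 * np.pi * t / 2.0))
        with pytest.raises(ValueError, match="static pose"):
            reg.detect_box_pose_window(s)

    def test_too_short_series_fails(self):
        s = AngleSeries(np.arange(10) / 50.0, np.zeros(10))
        with pytest.raises(ValueError, match="short"):
            reg.detect_box_pose_window(s, min_duration=2.0)

    def test_noisy_flat_segment_matches_bruteforce(self):
        """A flat segment with 0.2-deg noise qualifies at a 0.5-deg threshold,
        and an explicit-loop recomputation finds the same longest run."""
        series = _flat_then_motion(noise_sd=0.2, seed=1)
        t0, t1 = reg.detect_box_pose_window(series, min_duration=2.0, stillness_sd=0.5)
        win = int(round(2.0 * 50))
        ok = np.array([
            np.std(series.angle[i - win + 1: i + 1], ddof=1) < 0.5 if i >= win - 1 else False
            for i in range(len(series))
        ])
        runs, start = [], None
        for i, v in enumerate(ok):
            if v and start is None:
                start = i
            if not v and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(ok)))
        bs, be = max(runs, key=lambda r: r[1] - r[0])
        assert t0 == pytest.approx(series.t[max(0, bs - win + 1)])
        assert t1 == pytest.approx(series.t[be - 1])


class TestComputeOffset:
    def test_constant_arithmetic(self):
        s = AngleSeries(np.arange(100) / 50.0, np.full(100, 80.0))
        off = reg.compute_offset(s, (0.0, 1.0), reg.GoniometerReading(60.0))
        assert off.delta_knee == pytest.approx(20.0)

    def test_zero_offset_identity(self):
        s = AngleSeries(np.arange(100) / 50.0, np.full(100, 60.0))
        off = reg.compute_offset(s, (0.0, 1.0), reg.GoniometerReading(60.0))
        assert off.delta_knee == pytest.approx(0.0)

    def test_recovers_injected_misalignment(self, nf_result):
        # delta_F = 5, delta_T = -3, no goniometer error => delta_knee = 8
        assert nf_result["offset"].delta_knee == pytest.approx(8.0, abs=0.1)

    def test_rejects_bad_windows(self):
        s = AngleSeries(np.arange(100) / 50.0, np.full(100, 60.0))
        with pytest.raises(ValueError):
            reg.compute_offset(s, (10.0, 12.0), reg.GoniometerReading(60.0))
        withnan = AngleSeries(np.arange(100) / 50.0, np.full(100, 60.0))
        withnan.angle[10] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            reg.compute_offset(withnan, (0.0, 1.0), reg.GoniometerReading(60.0))


class TestApplyOffset:
    def test_pointwise_subtraction(self):
        s = AngleSeries(np.arange(10) / 50.0, np.full(10, 80.0))
        out = reg.apply_offset(s, reg.RegistrationOffset(20.0, (0, 1)))
        assert np.all(out.angle == 60.0)
        ident = reg.apply_offset(s, reg.RegistrationOffset(0.0, (0, 1)))
        assert np.all(ident.angle == s.angle)

    def test_window_mean_equals_goniometer_after_round_trip(self):
        rng = np.random.default_rng(2)
        s = AngleSeries(np.arange(300) / 50.0, 70 + rng.normal(0, 0.3, 300))
        gonio = reg.GoniometerReading(61.0)
        off = reg.compute_offset(s, (0.0, 5.0), gonio)
        corrected = reg.apply_offset(s, off)
        m = corrected.angle[corrected.window_mask(0.0, 5.0)].mean()
        assert m == pytest.approx(61.0, abs=1e-12)

    def test_reregistration_idempotent(self):
        rng = np.random.default_rng(3)
        s = AngleSeries(np.arange(300) / 50.0, 70 + rng.normal(0, 0.3, 300))
        gonio = reg.GoniometerReading(61.0)
        off = reg.compute_offset(s, (0.0, 5.0), gonio)
        corrected = reg.apply_offset(s, off)
        off2 = reg.compute_offset(corrected, (0.0, 5.0), gonio)
        assert abs(off2.delta_knee) < 1e-9

    def test_end_to_end_matches_truth(self, nf_result):
        sensor = nf_result["sensor"]
        truth = nf_result["session"].truth
        err = sensor.angle - truth.alpha_knee_true
        assert np.abs(err).max() < 0.3  # filter tolerance, noise-free


class TestInvariants:
    @settings(derandomize=True, max_examples=50)
    @given(
        alpha_pt=st.floats(min_value=0.0, max_value=160.0),
        level=st.floats(min_value=-60.0, max_value=160.0),
        spread=st.floats(min_value=0.0, max_value=2.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_round_trip_anchors_window_mean(self, alpha_pt, level, spread, seed):
        """For any series and goniometer reading, registering and applying
        the offset makes the window mean equal the reading exactly."""
        rng = np.random.default_rng(seed)
        s = AngleSeries(np.arange(200) / 50.0, level + rng.normal(0, spread, 200))
        off = reg.compute_offset(s, (0.0, 2.0), reg.GoniometerReading(alpha_pt))
        out = reg.apply_offset(s, off)
        m = out.angle[out.window_mask(0.0, 2.0)].mean()
        assert m == pytest.approx(alpha_pt, abs=1e-9)

    def test_misalignment_cancellation(self):
        """Registered knee angle depends on (delta_F, delta_T) only through
        their difference."""
        a = run_synthetic_session(
            make_scenario(profile=kf.MotionProfile(duration=8.0),
                          mounts=kf.SensorMountSpec(delta_f=5.0, delta_t=-3.0)),
            fit_piecewise=False)
        b = run_synthetic_session(
            make_scenario(profile=kf.MotionProfile(duration=8.0),
                          mounts=kf.SensorMountSpec(delta_f=12.0, delta_t=4.0)),
            fit_piecewise=False)
        diff = a["sensor"].angle - b["sensor"].angle
        assert np.abs(diff).max() < 0.1

    def test_goniometer_error_shifts_output_by_constant(self):
        base = run_synthetic_session(
            make_scenario(profile=kf.MotionProfile(duration=8.0), goniometer_error=0.0),
            fit_piecewise=False)
        off = run_synthetic_session(
            make_scenario(profile=kf.MotionProfile(duration=8.0), goniometer_error=2.0),
            fit_piecewise=False)
        # alpha_PT reads 2 deg high -> every reported angle is 2 deg high
        shift = off["sensor"].angle - base["sensor"].angle
        assert np.abs(shift - 2.0).max() < 1e-9
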