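"""Binned bias statistics, agreement fits, piecewise bias model, repeatability."""

import numpy as np
import pytest

from kneeflex import bias, reference_data
from kneeflex.align import AlignedPair


def _pair(sensor, video, rate=60.0):
    sensor = np.asarray(sensor, dtype=float)
    return AlignedPair(np.arange(sensor.size) / rate, sensor, np.asarray(video, float), 0, rate)


class TestBinnedBias:
    def test_single_bin_hand_arithmetic(self):
        pair = _pair([12.0, 13.0], [11.0, 14.0])  # biases +1, -1
        tab = bias.binned_bias_table(pair).table
        row = tab[tab["n"] > 0].iloc[0]
        assert row["n"] == 2
        assert row["mean_bias"] == pytest.approx(0.0)
        assert row["mae"] == pytest.approx(1.0)

    def test_boundary_goes_to_upper_bin(self):
        pair = _pair([5.0], [5.0])
        tab = bias.binned_bias_table(pair).table
        row = tab[tab["n"] > 0].iloc[0]
        assert (row["bin_left"], row["bin_right"]) == (5.0, 10.0)

    def test_matches_bruteforce_on_random_data(self):
        rng = np.random.default_rng(5)
        sensor = rng.uniform(-3.0, 112.0, 10_000)
        vid = sensor - rng.normal(0.5, 3.0, sensor.size)
        pair = _pair(sensor, vid)
        result = bias.binned_bias_table(pair)
        tab = result.table
        in_span = 0
        for _, row in tab.iterrows():
            sel = (sensor >= row["bin_left"]) & (sensor < row["bin_right"])
            b = (sensor - vid)[sel]
            assert row["n"] == sel.sum()
            if sel.sum():
                in_span += sel.sum()
                assert row["mean_bias"] == pytest.approx(b.mean())
                assert row["mae"] == pytest.approx(np.abs(b).mean())
                assert row["sd"] == pytest.approx(b.std(ddof=1))
                lo, hi = np.percentile(b, [2.5, 97.5])
                assert row["p95_range"] == pytest.approx(hi - lo)
                assert row["mae"] >= abs(row["mean_bias"]) - 1e-12
        # bin conservation: every sample lands in exactly one bin
        assert result.n_total == sensor.size == in_span

    def test_overall_single_bin(self):
        pair = _pair([12.0, 13.0], [11.0, 14.0])
        mean_b, mae = bias.overall_summary(bias.binned_bias_table(pair))
        assert mean_b == pytest.approx(0.0)
        assert mae == pytest.approx(1.0)


class TestLinearAgreement:
    def test_identity(self):
        x = np.linspace(0, 100, 50)
        fit = bias.fit_linear_agreement(_pair(x, x))
        assert (fit.slope, fit.intercept, fit.r_squared) == pytest.approx((1.0, 0.0, 1.0))

    def test_exact_affine(self):
        v = np.linspace(0, 100, 50)
        fit = bias.fit_linear_agreement(_pair(1.1 * v + 2.0, v))
        assert fit.slope == pytest.approx(1.1)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(0, 110, 500)
        s = 1.05 * v - 0.8 + rng.normal(0, 2.5, v.size)
        fit = bias.fit_linear_agreement(_pair(s, v))
        A = np.column_stack([np.ones_like(v), v])
        intercept, slope = np.linalg.solve(A.T @ A, A.T @ s)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            bias.fit_linear_agreement(_pair([1, 2, 3], [5, 5, 5]))

    def test_session_fit_on_synthetic_data(self, noisy_result):
        fit = noisy_result["linear_fit"]
        assert fit.r_squared > 0.99
        assert fit.slope == pytest.approx(1.0, abs=0.05)


def _truth_model():
    """A continuous 3-segment model with breakpoints 15 and 47 deg, built
    from hinge coefficients so continuity is exact."""
    bps = np.array([15.0, 47.0])
    coef = np.array([4.4, -0.23, 0.22, -0.05])  # intercept, slope, 2 hinges

    def predict(x):
        x = np.asarray(x, dtype=float)
        return (coef[0] + coef[1] * x + coef[2] * np.maximum(0, x - bps[0])
                + coef[3] * np.maximum(0, x - bps[1]))

    slopes = [coef[1], coef[1] + coef[2], coef[1] + coef[2] + coef[3]]
    return bps, slopes, predict


class TestPiecewiseFit:
    def test_exact_recovery_over_seeds(self):
        """Noise-free data from a known 3-segment model is recovered to
        within 1 deg on breakpoints and 0.01 on slopes, for every seed."""
        bps, slopes, predict = _truth_model()
        x = np.arange(2.5, 110.0, 5.0)
        y = predict(x)
        for seed in range(20):
            model = bias.fit_piecewise_bias(np.column_stack([x, y]), seed=seed)
            assert np.abs(model.breakpoints - bps).max() < 1.0
            got = [s for _, s in model.segments]
            assert np.abs(np.array(got) - slopes).max() < 0.01
            assert model.r_squared > 0.999

    def test_collinear_points_degenerate(self):
        x = np.linspace(0, 100, 30)
        y = 0.5 * x - 3.0
        model = bias.fit_piecewise_bias(np.column_stack([x, y]), seed=0)
        s = [sl for _, sl in model.segments]
        assert np.ptp(s) < 1e-6
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_bin_means_give_weak_fit(self):
        """Per-(session, bin) mean points with bin-level noise comparable to
        the observed per-bin SDs produce a clearly imperfect fit."""
        bps, slopes, predict = _truth_model()
        centers = reference_data.BINNED_BIAS["bin_center"].to_numpy()
        sds = reference_data.BINNED_BIAS["sd"].to_numpy()
        rng = np.random.default_rng(99)
        xs, ys = [], []
        for _ in range(20):  # one set of bin means per exercise session
            xs.append(centers)
            ys.append(predict(centers) + rng.normal(0, sds))
        pts = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
        model = bias.fit_piecewise_bias(pts, seed=0)
        assert 0.2 < model.r_squared < 0.6

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            bias.fit_piecewise_bias([(0, 1), (1, 2), (2, 3)], n_segments=3)


class TestPiecewiseCorrection:
    def test_zero_model_is_identity(self):
        pair = _pair([10.0, 60.0, 100.0], [9.0, 61.0, 98.0])
        model = bias.PiecewiseLinearModel([15.0, 47.0], [(0, 0), (0, 0), (0, 0)], 1.0)
        out = bias.apply_piecewise_correction(pair, model)
        assert np.array_equal(out.sensor, pair.sensor)
        assert np.array_equal(out.video, pair.video)

    def test_published_third_segment_arithmetic(self):
        """With the published model, a 60-deg reading has predicted bias
        2.71 - 0.06 * 60 = -0.89, so the corrected angle is 60.89."""
        model = bias.PiecewiseLinearModel(
            reference_data.PIECEWISE_BREAKPOINTS,
            reference_data.PIECEWISE_SEGMENTS,
        )
        assert model.predict(60.0) == pytest.approx(-0.89)
        pair = _pair([60.0], [60.0])
        out = bias.apply_piecewise_correction(pair, model)
        assert out.sensor[0] == pytest.approx(60.89)

    def test_exact_cancellation(self):
        bps, slopes, predict = _truth_model()
        model = bias.fit_piecewise_bias(
            np.column_stack([np.arange(2.5, 110, 5), predict(np.arange(2.5, 110, 5))]),
            seed=1)
        sensor = np.linspace(1.0, 109.0, 400)
        pair = _pair(sensor, sensor - model.predict(sensor))
        out = bias.apply_piecewise_correction(pair, model)
        assert np.abs(out.bias).max() < 1e-9

    def test_correction_reduces_angle_dependent_bias(self):
        """Fit + correction strictly shrinks the overall mean bias when the
        injected bias varies with angle."""
        bps, slopes, predict = _truth_model()
        rng = np.random.default_rng(3)
        sensor = rng.uniform(0.0, 110.0, 5000)
        pair = _pair(sensor, sensor - predict(sensor) - rng.normal(0, 1.0, sensor.size))
        model = bias.fit_piecewise_bias(np.column_stack([pair.sensor, pair.bias]), seed=0)
        corrected = bias.apply_piecewise_correction(pair, model)
        before, _ = bias.overall_summary(bias.binned_bias_table(pair))
        after, _ = bias.overall_summary(bias.binned_bias_table(corrected))
        assert abs(after) < abs(before)


class TestRepeatability:
    def test_goniometer_toy_oracle(self):
        rep = bias.goniometer_repeatability({1: (60, 64), 2: (55, 54), 3: (70, 70)})
        assert rep.pooled_mean == pytest.approx((4 + 1 + 0) / 3)
        assert rep.reading_min == 54 and rep.reading_max == 70

    def test_goniometer_identical_visits(self):
        rep = bias.goniometer_repeatability({i: (60, 60) for i in range(5)})
        assert rep.pooled_mean == 0.0

    def test_goniometer_missing_visit_rejected(self):
        with pytest.raises(ValueError, match="both visits"):
            bias.goniometer_repeatability({1: (60, None)})

    def test_pose_toy_bruteforce(self):
        offsets = {"a": [[10.0, 12.0, 11.0]], "b": [[5.0, 5.0], [8.0, 6.0]]}
        rep = bias.pose_repeatability(offsets)
        a = np.abs(np.array([10, 12, 11]) - 11.0)
        b = np.abs(np.concatenate([[0.0, 0.0], np.array([8, 6]) - 7.0]))
        assert rep.per_patient.set_index("patient").loc["a", "mean_abs"] == pytest.approx(a.mean())
        assert rep.per_patient.set_index("patient").loc["b", "max_abs"] == pytest.approx(b.max())
        expected_pool = (a.mean() * 3 + b.mean() * 4) / 7
        assert rep.pooled_mean == pytest.approx(expected_pool)

    def test_pose_identical_repeats_and_flagging(self):
        rep = bias.pose_repeatability({"a": [[7.0, 7.0, 7.0]], "b": [[3.0]]})
        assert rep.pooled_mean == 0.0
        assert rep.flagged == [("b", 0)]
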