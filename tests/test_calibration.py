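"""Gain, affine-registration and drift estimation against exact oracles."""

import numpy as np
import pytest

from cosmotrace import calibration as cal
from cosmotrace import synthetic as syn
from cosmotrace.stacks import MovieStack


def _constant_var_stack(mean, var, n=50, shape=(8, 8), seed=0):
    """Stack whose temporal mean and ddof=1 variance are exact by design."""
    half = n // 2
    sd = np.sqrt(var * (n - 1) / n)
    frames = np.concatenate([np.full((half, *shape), mean - sd),
                             np.full((half, *shape), mean + sd)])
    return MovieStack(frames)


class TestGain:
    def test_two_point_line_recovers_gain_and_offset(self):
        # (mean 100, var 0) dark and (mean 300, var 400) -> slope 2, offset 100
        bright = _constant_var_stack(300.0, 400.0)
        dark = _constant_var_stack(100.0, 0.0)
        cc = cal.estimate_gain([bright], dark, hot_pixel_fraction=0.0)
        assert cc.gain == pytest.approx(2.0, abs=1e-9)
        assert cc.offset == pytest.approx(100.0)

    def test_simulated_stacks_recover_gain_within_5pct(self):
        cam = syn.CameraModel(gain=30.0, offset=100.0)
        stacks, dark = syn.simulate_calibration_stacks(
            cam, [10.0, 50.0, 100.0], 200, (32, 32), seed=21)
        cc = cal.estimate_gain(stacks, dark)
        assert abs(cc.gain / 30.0 - 1.0) < 0.05
        assert abs(cc.offset - 100.0) < 1.0

    def test_estimator_consistency_with_frame_count(self):
        cam = syn.CameraModel(gain=20.0, offset=50.0)
        errs = []
        for frames in (50, 200, 800):
            stacks, dark = syn.simulate_calibration_stacks(
                cam, [20.0, 80.0], frames, (24, 24), seed=22)
            errs.append(abs(cal.estimate_gain(stacks, dark).gain - 20.0))
        assert errs[2] < errs[0]

    def test_single_level_raises_insufficient_dynamic_range(self):
        dark = _constant_var_stack(100.0, 0.0)
        with pytest.raises(cal.CalibrationError, match="dynamic range"):
            cal.estimate_gain([_constant_var_stack(100.0, 0.0)], dark)

    def test_counts_to_photons_inverse_of_camera_model(self):
        cc = cal.CameraCalibration(gain=2.0, offset=100.0)
        stack = MovieStack(np.full((2, 4, 4), 100.0))
        assert np.all(cal.counts_to_photons(stack, cc).data == 0.0)
        stack2 = MovieStack(np.full((2, 4, 4), 100.0 + 2.0 * 7))
        assert np.allclose(cal.counts_to_photons(stack2, cc).data, 7.0)

    def test_round_trip_photon_mean(self):
        cam = syn.CameraModel(gain=30.0, offset=100.0)
        stacks, dark = syn.simulate_calibration_stacks(
            cam, [100.0], 200, (16, 16), seed=23)
        cc = cal.CameraCalibration(gain=30.0, offset=100.0)
        photons = cal.counts_to_photons(stacks[0], cc)
        assert abs(photons.data.mean() / 100.0 - 1.0) < 0.02


class TestAffine:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 2))
        m = cal.fit_affine_map(pts, pts)
        np.testing.assert_allclose(m.matrix, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(m.translation, 0.0, atol=1e-10)
        assert m.rms_residual < 1e-12

    def test_exact_recovery_of_known_transform(self):
        th = np.deg2rad(1.0)
        A = 1.01 * np.array([[np.cos(th), -np.sin(th)],
                             [np.sin(th), np.cos(th)]])
        pts = np.random.default_rng(1).uniform(0, 100, (20, 2))
        m = cal.fit_affine_map(pts, pts @ A.T + [2.0, 3.0])
        np.testing.assert_allclose(m.matrix, A, atol=1e-9)
        np.testing.assert_allclose(m.translation, [2.0, 3.0], atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0, 50, (12, 2))
        p2 = p1 @ np.array([[1.02, 0.01], [-0.02, 0.98]]).T + [1, -2] \
            + rng.normal(0, 0.1, (12, 2))
        m = cal.fit_affine_map(p1, p2)
        X = np.column_stack([p1, np.ones(len(p1))])
        coef = np.linalg.solve(X.T @ X, X.T @ p2)   # normal equations
        np.testing.assert_allclose(m.matrix, coef[:2].T, atol=1e-8)
        np.testing.assert_allclose(m.translation, coef[2], atol=1e-8)

    def test_noisy_beads_residual_bounded(self):
        m_true = cal.AffineMap(np.eye(2) * 1.01, [2.0, 3.0])
        out = syn.simulate_bead_field(50, m_true, 0.1, seed=24)
        m = cal.fit_affine_map(out["coords_ch1"], out["coords_ch2"])
        assert m.rms_residual <= 0.2

    def test_collinear_configuration_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises(cal.CalibrationError, match="rank-deficient"):
            cal.fit_affine_map(pts, pts)

    def test_unmatched_correspondence_via_mutual_nn(self):
        m_true = cal.AffineMap(np.eye(2), [1.5, -0.8])
        out = syn.simulate_bead_field(30, m_true, 0.01, seed=25)
        perm = np.random.default_rng(3).permutation(30)
        m = cal.fit_affine_map(out["coords_ch1"], out["coords_ch2"][perm],
                               matched=False)
        np.testing.assert_allclose(m.translation, [1.5, -0.8], atol=0.05)

    def test_inverse_roundtrip(self):
        m = cal.AffineMap(np.array([[1.01, 0.02], [-0.01, 0.99]]), [2.0, 3.0])
        pts = np.random.default_rng(4).uniform(0, 64, (10, 2))
        np.testing.assert_allclose(m.inverse().apply(m.apply(pts)), pts,
                                   atol=1e-9)


class TestDrift:
    def _spot_field(self, rng, shift=(0.0, 0.0)):
        spots = [(x + shift[0], y + shift[1], 2000.0, 1.3)
                 for x, y in rng.uniform(10, 54, (20, 2))]
        from cosmotrace.psf import render_scene_frame
        return rng.poisson(render_scene_frame((64, 64), spots, 5.0)).astype(float)

    def test_identical_frames_zero_drift(self):
        rng = np.random.default_rng(5)
        f = self._spot_field(rng)
        track = cal.estimate_drift(MovieStack(np.stack([f, f, f])))
        np.testing.assert_allclose(track.dx, 0.0, atol=1e-9)
        np.testing.assert_allclose(track.dy, 0.0, atol=1e-9)

    def test_integer_shift_recovered_exactly(self):
        rng = np.random.default_rng(6)
        f = self._spot_field(rng)
        g = np.roll(np.roll(f, -2, axis=0), 3, axis=1)    # dx=+3, dy=-2
        track = cal.estimate_drift(MovieStack(np.stack([f, g])))
        assert track.dx[1] == pytest.approx(3.0, abs=0.05)
        assert track.dy[1] == pytest.approx(-2.0, abs=0.05)

    def test_subpixel_shift_error_below_tenth_pixel(self):
        rng = np.random.default_rng(7)
        f0 = self._spot_field(rng)
        rng = np.random.default_rng(7)
        f1 = self._spot_field(rng, shift=(0.5, 0.0))
        track = cal.estimate_drift(MovieStack(np.stack([f0, f1])))
        assert abs(track.dx[1] - 0.5) < 0.1
        assert abs(track.dy[1]) < 0.1

    def test_linear_drift_mean_error_small(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            coords = rng.uniform(10, 54, (20, 2))
            frames = []
            per_frame = 0.3
            for t in range(4):
                from cosmotrace.psf import render_scene_frame
                spots = [(x + per_frame * t, y, 2000.0, 1.3) for x, y in coords]
                frames.append(rng.poisson(
                    render_scene_frame((64, 64), spots, 5.0)).astype(float))
            track = cal.estimate_drift(MovieStack(np.stack(frames)))
            errs.append(track.dx[3] - 3 * per_frame)
        assert abs(np.mean(errs)) < 0.05

    def test_apply_unapply_roundtrip(self):
        track = cal.DriftTrack(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        m = cal.AffineMap(np.eye(2) * 1.01, [2.0, 3.0])
        pts = np.array([[10.0, 20.0], [30.0, 5.0]])
        back = cal.apply_corrections(
            cal.unapply_corrections(pts, 1, track, m), 1, track, m)
        np.testing.assert_allclose(back, pts, atol=1e-12)

    def test_frame_out_of_range_rejected(self):
        track = cal.DriftTrack.zero(3)
        with pytest.raises(IndexError):
            cal.apply_corrections(np.zeros((1, 2)), 5, track)
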