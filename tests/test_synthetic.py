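"""Simulator contracts: noise statistics, determinism, ground-truth fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cosmotrace import calibration as cal
from cosmotrace import synthetic as syn


class TestCameraModel:
    def test_dark_frames_have_offset_mean_and_no_variance(self):
        cam = syn.CameraModel(gain=2.0, offset=100.0, read_noise_sd=0.0)
        _, dark = syn.simulate_calibration_stacks(cam, [5.0], 10, (16, 16), seed=0)
        assert np.allclose(dark.data, 100.0)

    def test_mean_variance_linearity_slope_is_gain(self):
        # scaled Poisson: Var = gain^2 * lam = gain * (mean - offset)
        cam = syn.CameraModel(gain=30.0, offset=100.0)
        stacks, dark = syn.simulate_calibration_stacks(
            cam, [10.0, 50.0, 100.0], 200, (32, 32), seed=1)
        means = [s.data.mean() for s in stacks] + [dark.data.mean()]
        variances = [s.data.var(ddof=1) for s in stacks] + [dark.data.var(ddof=1)]
        slope = stats.linregress(means, variances).slope
        assert abs(slope / 30.0 - 1.0) < 0.05

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(syn.SimulationError):
            syn.CameraModel(gain=0.0)

    def test_canonical_hundred_frame_calibration_input(self):
        cam = syn.CameraModel()
        stacks, dark = syn.simulate_calibration_stacks(
            cam, [50.0], 100, (8, 8), seed=2)
        assert stacks[0].n_frames == 100 and dark.n_frames == 100


class TestBeadField:
    def test_identity_map_zero_noise_gives_identical_coordinates(self):
        out = syn.simulate_bead_field(10, cal.AffineMap.identity(), 0.0, seed=3)
        np.testing.assert_allclose(out["coords_ch1"], out["coords_ch2"])

    def test_known_transform_applied_exactly(self):
        th = np.deg2rad(1.0)
        m = cal.AffineMap(1.01 * np.array([[np.cos(th), -np.sin(th)],
                                           [np.sin(th), np.cos(th)]]), [2.0, 3.0])
        out = syn.simulate_bead_field(15, m, 0.0, seed=4)
        np.testing.assert_allclose(out["coords_ch2"],
                                   m.apply(out["coords_ch1"]), atol=1e-12)

    def test_too_few_beads_rejected(self):
        with pytest.raises(syn.SimulationError):
            syn.simulate_bead_field(2, cal.AffineMap.identity(), 0.0, seed=0)


class TestTraces:
    def test_canonical_dataset_size_400x1500(self, default_truth):
        import time
        t0 = time.perf_counter()
        table, states = syn.simulate_traces(default_truth, 400, 1500, seed=5)
        elapsed = time.perf_counter() - t0
        assert len(table) == 600_000
        assert states.shape == (400, 1500)
        assert elapsed < 5.0

    def test_single_state_zero_covariance_constant(self):
        truth = syn.TraceGroundTruth(np.eye(1), means=[[7.0, 3.0]],
                                     covs=np.zeros((2, 2)))
        table, _ = syn.simulate_traces(truth, 2, 50, seed=6)
        assert np.allclose(table["signal"], 7.0)
        assert np.allclose(table["background"], 3.0)

    def test_non_stochastic_transition_rejected(self):
        with pytest.raises(syn.SimulationError):
            syn.TraceGroundTruth(np.array([[0.5, 0.2], [0.5, 0.5]]),
                                 means=[[0.0], [1.0]], covs=np.zeros((1, 1)))

    def test_empirical_transition_frequencies_match(self):
        trans = np.array([[0.95, 0.05], [0.10, 0.90]])
        truth = syn.TraceGroundTruth(trans, means=[[0.0], [1.0]],
                                     covs=np.zeros((1, 1)))
        rng = np.random.default_rng(7)
        states = syn.simulate_state_sequences(truth, 1, 100_000, rng)[0]
        for i in range(2):
            at_i = states[:-1] == i
            n_i = at_i.sum()
            p_hat = (states[1:][at_i] != i).mean()
            p_true = trans[i, 1 - i]
            se = np.sqrt(p_true * (1 - p_true) / n_i)
            assert abs(p_hat - p_true) < 3 * se

    def test_dwell_times_are_geometric(self, default_truth):
        # dwell at top occupancy has geometric law with the self-exit prob
        rng = np.random.default_rng(8)
        states = syn.simulate_state_sequences(default_truth, 10, 10_000, rng)
        dwells = []
        for s in states:
            run = 1
            for a, b in zip(s[:-1], s[1:]):
                if a == b == 2:
                    run += 1
                elif a == 2:
                    dwells.append(run)
                    run = 1
        p_exit = 1.0 - default_truth.transition[2, 2]
        ks = stats.kstest(dwells, stats.geom(p_exit).cdf)
        assert ks.pvalue > 0.01

    def test_fixed_seed_reproducibility(self, default_truth):
        a, sa = syn.simulate_traces(default_truth, 5, 100, seed=9)
        b, sb = syn.simulate_traces(default_truth, 5, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)
        np.testing.assert_array_equal(sa, sb)


class TestBootstrapSubsets:
    def test_methods_size_ladder_supported(self, default_truth):
        table, _ = syn.simulate_traces(default_truth, 400, 1500, seed=10)
        sizes = [750, 6000, 12000, 18000, 24000, 30000, 60000,
                 120000, 240000, 360000, 480000]
        subs = syn.bootstrap_subsets(table, sizes, seed=0)
        assert [len(s) for s in subs] == sizes

    def test_zero_size_rejected(self, default_truth):
        table, _ = syn.simulate_traces(default_truth, 2, 10, seed=0)
        with pytest.raises(syn.SimulationError):
            syn.bootstrap_subsets(table, [0], seed=0)

    def test_fixed_seed_gives_identical_subsets(self, default_truth):
        table, _ = syn.simulate_traces(default_truth, 10, 50, seed=1)
        a = syn.bootstrap_subsets(table, [100, 200], seed=3)
        b = syn.bootstrap_subsets(table, [100, 200], seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestBindingMovie:
    def test_drift_trajectory_recorded_in_ground_truth(self):
        drift = np.cumsum(np.full((100, 2), [0.01, 0.0]), axis=0)
        drift[0] = 0
        scene = syn.Scene((32, 32), [[16.0, 16.0, 500.0, 1.3]],
                          background=2.0, drift=drift)
        out = syn.simulate_binding_movie(scene, None, syn.CameraModel(),
                                         100, seed=0)
        t = out["truth"]
        last = t[t["frame"] == 99].iloc[0]
        assert last["x"] == pytest.approx(16.0 + drift[99, 0])

    def test_empty_scene_is_pure_background(self):
        scene = syn.Scene((16, 16), np.empty((0, 4)), background=5.0)
        out = syn.simulate_binding_movie(scene, None, syn.CameraModel(
            gain=1.0, offset=0.0), 20, seed=1)
        lam = out["target"].data.mean()
        assert abs(lam - 5.0) < 3 * np.sqrt(5.0 / (20 * 256))

    def test_drift_length_mismatch_rejected(self):
        scene = syn.Scene((16, 16), [[8.0, 8.0, 100.0, 1.3]],
                          drift=np.zeros((5, 2)))
        with pytest.raises(syn.SimulationError):
            syn.simulate_binding_movie(scene, None, syn.CameraModel(), 10, seed=0)

    def test_spot_outside_field_rejected(self):
        with pytest.raises(syn.SimulationError):
            syn.Scene((16, 16), [[20.0, 8.0, 100.0, 1.3]])
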