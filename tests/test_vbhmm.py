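"""VBEM-MGHMM: bound correctness, parameter recovery, order selection,
occupancy kinetics."""

import numpy as np
import pytest
from scipy.special import gammaln

from cosmotrace import synthetic as syn
from cosmotrace import vbhmm


def _nw_log_z(kappa, nu, W):
    """Normalizer of the Normal-Wishart density (precision parameterization)."""
    D = W.shape[0]
    mvg = D * (D - 1) / 4 * np.log(np.pi) \
        + sum(gammaln(nu / 2 + (1 - j) / 2) for j in range(1, D + 1))
    return (D / 2) * np.log(2 * np.pi / kappa) + (nu * D / 2) * np.log(2) \
        + mvg + (nu / 2) * np.linalg.slogdet(W)[1]


class TestElboAndK1:
    def test_elbo_nondecreasing_on_real_fit(self, small_traces):
        obs, _ = small_traces
        priors = vbhmm.MGHMMPriors(m=np.array([390.0, 200.0]))
        post = vbhmm.vbem_fit(obs[:30], 3, priors, restarts=2, seed=0)
        diffs = np.diff(post.elbo_trace)
        assert (diffs >= -1e-6 * np.abs(post.elbo_trace[:-1])).all()

    def test_k1_posterior_and_elbo_match_closed_form(self):
        """For K=1 the variational bound is tight: ELBO = exact log evidence
        of the conjugate Normal-Wishart model, and the posterior equals the
        exact conjugate update."""
        rng = np.random.default_rng(71)
        X = rng.normal([300.0, 50.0], [20.0, 5.0], size=(200, 2))
        priors = vbhmm.MGHMMPriors(m=np.array([280.0, 60.0]))
        post = vbhmm.vbem_fit([X], 1, priors, restarts=1, seed=0)

        N, D = X.shape
        k0, n0, W0 = priors.kappa, priors.nu, priors.W0()
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar)
        kN, nN = k0 + N, n0 + N
        WN = np.linalg.inv(np.linalg.inv(W0) + S
                           + (k0 * N / (k0 + N))
                           * np.outer(xbar - priors.m, xbar - priors.m))
        lml = -(N * D / 2) * np.log(2 * np.pi) \
            + _nw_log_z(kN, nN, WN) - _nw_log_z(k0, n0, W0)

        assert post.elbo == pytest.approx(lml, abs=1e-8 * abs(lml))
        np.testing.assert_allclose(post.m[0], (k0 * priors.m + N * xbar) / kN,
                                   rtol=1e-10)
        np.testing.assert_allclose(post.W[0], WN, rtol=1e-8)
        assert post.kappa[0] == pytest.approx(kN)
        assert post.nu[0] == pytest.approx(nN)

    def test_invalid_priors_rejected(self):
        with pytest.raises(vbhmm.VBEMError):
            vbhmm.MGHMMPriors(m=np.zeros(2), kappa=-1.0)
        with pytest.raises(vbhmm.VBEMError):
            vbhmm.MGHMMPriors(m=np.zeros(2), nu=0.5)


class TestRecovery:
    def test_two_separated_states_recovered(self):
        trans = np.array([[0.95, 0.05], [0.08, 0.92]])
        truth = syn.TraceGroundTruth(trans, means=[[100.0, 50.0],
                                                   [400.0, 50.0]],
                                     covs=np.diag([60.0**2, 20.0**2]))
        table, states = syn.simulate_traces(truth, 10, 1000, seed=72)
        obs = np.stack([table[table["trace"] == i]
                        [["signal", "background"]].to_numpy()
                        for i in range(10)])
        priors = vbhmm.MGHMMPriors(m=np.array([250.0, 50.0]))
        post = vbhmm.vbem_fit(obs, 2, priors, restarts=2, seed=1)
        means = post.expected_means()
        assert abs(means[0, 0] / 100.0 - 1.0) < 0.02
        assert abs(means[1, 0] / 400.0 - 1.0) < 0.02
        a = post.expected_transition()
        for i in range(2):
            n_i = (states[:, :-1] == i).sum()
            se = np.sqrt(trans[i, 1 - i] * (1 - trans[i, 1 - i]) / n_i)
            assert abs(a[i, 1 - i] - trans[i, 1 - i]) < 3 * se

    def test_three_state_decoding_accuracy(self, small_traces, default_truth):
        obs, states = small_traces
        priors = vbhmm.MGHMMPriors(m=np.array([390.0, 200.0]))
        post = vbhmm.vbem_fit(obs, 3, priors, restarts=2, seed=2)
        labels = np.stack(vbhmm.decode_states(post, obs))
        assert (labels == states).mean() >= 0.95

    def test_noiseless_two_level_signal_switchpoints_exact(self):
        seq = np.array([0] * 20 + [1] * 20 + [0] * 10)
        x = np.column_stack([100.0 + 300.0 * seq]).astype(float)
        x += np.random.default_rng(73).normal(0, 1e-3, x.shape)
        priors = vbhmm.MGHMMPriors(m=np.array([250.0]), nu=3.0)
        post = vbhmm.vbem_fit([x], 2, priors, restarts=2, seed=3)
        labels = vbhmm.decode_states(post, [x])[0]
        np.testing.assert_array_equal(labels, seq)

    def test_relabelling_orders_states_by_signal_mean(self, small_traces):
        obs, _ = small_traces
        priors = vbhmm.MGHMMPriors(m=np.array([390.0, 200.0]))
        post = vbhmm.vbem_fit(obs[:40], 3, priors, restarts=2, seed=4)
        means = post.expected_means()
        assert means[0, 0] < means[1, 0] < means[2, 0]


class TestOrderSelection:
    def test_single_state_data_selects_one(self):
        rng = np.random.default_rng(74)
        obs = [rng.normal([200.0, 50.0], [30.0, 10.0], size=(1500, 2))]
        priors = vbhmm.MGHMMPriors(m=np.array([200.0, 50.0]))
        k, _ = vbhmm.select_order(obs, range(1, 4), priors, restarts=2, seed=5)
        assert k == 1

    def test_three_state_data_selects_three_at_6000_points(self, default_truth):
        table, _ = syn.simulate_traces(default_truth, 4, 1500, seed=75)
        obs = [g[["signal", "background"]].to_numpy()
               for _, g in table.groupby("trace")]
        priors = vbhmm.MGHMMPriors(m=np.array([390.0, 200.0]))
        k, tab = vbhmm.select_order(obs, range(1, 5), priors, restarts=2,
                                    seed=6)
        assert k == 3
        assert tab[3].elbo > tab[2].elbo


class TestOccupancyRates:
    def test_independent_sites_ratios_from_true_labels(self, default_truth):
        rng = np.random.default_rng(76)
        states = syn.simulate_state_sequences(default_truth, 200, 1500, rng)
        occ = vbhmm.occupancy_rates(list(states), 0.1, seed=0)
        assert abs(occ["kon_ratio"] - 0.5) < 3 * occ["kon_ratio_se"] + 0.02
        assert abs(occ["koff_ratio"] - 2.0) < 3 * occ["koff_ratio_se"] + 0.08

    def test_single_site_traces_no_level2_no_crash(self):
        labels = [np.array([0, 1, 0, 1, 1, 0])]
        occ = vbhmm.occupancy_rates(labels, 0.1, n_boot=20, seed=1)
        assert np.isnan(occ["kon_ratio"]) and np.isnan(occ["koff_ratio"])
        assert occ["rate_up_per_s"][0] > 0

    def test_constant_zero_labels_all_rates_zero(self):
        occ = vbhmm.occupancy_rates([np.zeros(100, int)], 0.1, n_boot=10,
                                    seed=2)
        assert occ["rate_up_per_s"][0] == 0.0


class TestPriors:
    def test_defaults_are_ten(self):
        p = vbhmm.estimate_priors_from_traces(np.array([[300.0, 50.0]]))
        assert p.kappa == p.nu == p.W_sqrt == 10

    def test_m_from_single_event_frames(self):
        import pandas as pd
        traces = pd.DataFrame({
            "site_id": [0] * 6, "frame": range(6),
            "I_gf": [10.0, 300.0, 300.0, 300.0, 10.0, 10.0],
            "bg_est": [50.0] * 6})
        events = pd.DataFrame({"site_id": [0], "start_frame": [1],
                               "end_frame": [3]})
        p = vbhmm.estimate_priors_from_traces(traces, events)
        np.testing.assert_allclose(p.m, [300.0, 50.0])

    def test_two_events_pooled_mean(self):
        import pandas as pd
        traces = pd.DataFrame({
            "site_id": [0, 0, 1, 1], "frame": [0, 1, 0, 1],
            "I_gf": [200.0, 200.0, 400.0, 400.0],
            "bg_est": [40.0, 40.0, 60.0, 60.0]})
        events = pd.DataFrame({"site_id": [0, 1], "start_frame": [0, 0],
                               "end_frame": [1, 1]})
        p = vbhmm.estimate_priors_from_traces(traces, events)
        np.testing.assert_allclose(p.m, [300.0, 50.0])

    def test_no_events_raises(self):
        import pandas as pd
        with pytest.raises(vbhmm.VBEMError):
            vbhmm.estimate_priors_from_traces(
                pd.DataFrame({"site_id": [], "frame": [], "I_gf": [],
                              "bg_est": []}),
                pd.DataFrame())


class TestCrossChecks:
    def test_decoding_agrees_with_hmmlearn(self, default_truth):
        """Independent HMM implementation recovers the same segmentation."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        table, _ = syn.simulate_traces(default_truth, 5, 1000, seed=77)
        obs = [g[["signal", "background"]].to_numpy()
               for _, g in table.groupby("trace")]
        priors = vbhmm.MGHMMPriors(m=np.array([390.0, 200.0]))
        post = vbhmm.vbem_fit(obs, 3, priors, restarts=2, seed=7)
        ours = np.concatenate(vbhmm.decode_states(post, obs))

        X = np.concatenate(obs)
        gh = hmm.GaussianHMM(n_components=3, covariance_type="full",
                             n_iter=100, random_state=0, init_params="")
        gh.startprob_ = default_truth.stationary()  # oracle knows the truth
        gh.transmat_ = default_truth.transition.copy()
        gh.means_ = default_truth.means.copy()
        gh.covars_ = default_truth.covs.copy()
        gh.fit(X, lengths=[len(o) for o in obs])
        theirs = gh.predict(X, lengths=[len(o) for o in obs])
        order = np.argsort(gh.means_[:, 0])
        relabel = np.empty(3, int)
        relabel[order] = np.arange(3)
        assert (ours == relabel[theirs]).mean() > 0.98
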