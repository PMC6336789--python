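"""Censored-exponential kinetics, dark-site correction, bootstrap errors."""

import numpy as np
import pandas as pd
import pytest

from cosmotrace import kinetics as kin

BOOT = kin.BootstrapConfig(cycles=200, seed=1)


class TestCensoredExponential:
    def test_closed_form_rate(self):
        fit = kin.fit_exponential_censored([1.0, 2.0, 3.0])
        assert fit["rate"] == pytest.approx(0.5)

    def test_sampling_recovery_within_3se(self):
        rng = np.random.default_rng(51)
        t = rng.exponential(1 / 2.0, 1000)
        fit = kin.fit_exponential_censored(t)
        se = 2.0 / np.sqrt(1000)
        assert abs(fit["rate"] - 2.0) < 3 * se
        assert fit["ci_low"] < 2.0 < fit["ci_high"]

    def test_all_censored_unidentifiable(self):
        with pytest.raises(kin.KineticsError, match="unidentifiable"):
            kin.fit_exponential_censored([1.0, 2.0], censored=[True, True])

    def test_agrees_with_lifelines_oracle(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(52)
        t = rng.exponential(0.7, 300)
        cens = t > 1.0
        tt = np.minimum(t, 1.0)
        ours = kin.fit_exponential_censored(tt, cens)["rate"]
        ef = lifelines.ExponentialFitter().fit(tt, ~cens)
        assert ours == pytest.approx(1.0 / ef.lambda_, rel=1e-6)

    @pytest.mark.parametrize("k", [0.1, 0.61, 2.0, 18.0])
    def test_bias_under_5pct_with_censoring(self, k):
        """Relative bias of the censored MLE at n=1000, ~20% censoring,
        averaged over replicates so sampling scatter does not mask it."""
        rng = np.random.default_rng(int(k * 100))
        rel = []
        for _ in range(100):
            t = rng.exponential(1 / k, 1000)
            horizon = np.quantile(t, 0.8)
            cens = t > horizon
            fit = kin.fit_exponential_censored(np.minimum(t, horizon), cens)
            rel.append(fit["rate"] / k - 1.0)
        assert abs(np.mean(rel)) < 0.05


class TestKonKoff:
    def _arrivals(self, k_obs, n, seed, movie_s=None):
        rng = np.random.default_rng(seed)
        t = rng.exponential(1 / k_obs, n)
        movie_s = movie_s or np.inf
        cens = t > movie_s
        return pd.DataFrame({"site_id": range(n),
                             "arrival_s": np.minimum(t, movie_s),
                             "censored": cens})

    def test_kon_recovery_with_concentration(self):
        c = 100e-12
        tab = self._arrivals(0.007, 1000, seed=53)
        est = kin.estimate_kon(tab, c, BOOT)
        assert abs(est.k_on - 7e7) < 3 * est.se_kon

    def test_doubling_concentration_doubles_kobs(self):
        tab1 = self._arrivals(0.005, 2000, seed=54)
        tab2 = self._arrivals(0.010, 2000, seed=55)
        e1 = kin.estimate_kon(tab1, 1e-10, BOOT)
        e2 = kin.estimate_kon(tab2, 2e-10, BOOT)
        assert e2.extra["k_obs"] / e1.extra["k_obs"] == pytest.approx(2.0, rel=0.15)
        assert e1.k_on == pytest.approx(e2.k_on, rel=0.15)

    def test_bootstrap_se_tracks_analytic_se(self):
        n, k = 500, 2.0
        tab = self._arrivals(k, n, seed=56)
        est = kin.estimate_kon(tab, 1.0,
                               kin.BootstrapConfig(cycles=500, seed=2))
        analytic = k / np.sqrt(n)
        assert abs(est.se_kon / analytic - 1.0) < 0.25

    def test_single_cycle_full_fraction_deterministic(self):
        tab = self._arrivals(1.0, 50, seed=57)
        cfg = kin.BootstrapConfig(cycles=1, fraction=1.0, seed=3)
        a = kin.estimate_kon(tab, 1.0, cfg)
        b = kin.estimate_kon(tab, 1.0, cfg)
        assert a.se_kon == b.se_kon == 0.0 or a.se_kon == b.se_kon

    def test_koff_recovery(self):
        rng = np.random.default_rng(58)
        tab = pd.DataFrame({"site_id": range(1000),
                            "dwell_s": rng.exponential(1 / 0.61, 1000),
                            "dwell_censored": False})
        est = kin.estimate_koff(tab, boot=BOOT)
        assert abs(est.k_off - 0.61) < 3 * max(est.se_koff, 0.61 / np.sqrt(1000))

    def test_photobleach_limited_flagged_and_suppressed(self):
        rng = np.random.default_rng(59)
        tab = pd.DataFrame({"site_id": range(200),
                            "dwell_s": rng.exponential(1 / 0.01, 200),
                            "dwell_censored": False})
        est = kin.estimate_koff(tab, bleach_rate=0.05, boot=BOOT)
        assert est.photobleach_limited
        assert np.isnan(est.k_off)

    def test_empty_dwells_error(self):
        with pytest.raises(kin.KineticsError):
            kin.estimate_koff(pd.DataFrame({"site_id": [], "dwell_s": []}),
                              boot=BOOT)


class TestNonspecificCorrection:
    def _arr(self, k, n, seed, movie_s=100.0):
        rng = np.random.default_rng(seed)
        t = rng.exponential(1 / k, n)
        return pd.DataFrame({"site_id": range(n),
                             "arrival_s": np.minimum(t, movie_s),
                             "censored": t > movie_s})

    def test_zero_dark_events_identity(self):
        target = self._arr(0.05, 300, seed=60)
        dark = pd.DataFrame({"site_id": range(50), "arrival_s": 100.0,
                             "censored": True})
        out = kin.nonspecific_correction(target, dark, BOOT)
        assert out["dark_rate"] == 0.0
        assert out["corrected_rate"] == pytest.approx(out["target_rate"])

    def test_additive_nonspecific_rate_removed(self):
        # apparent target rate = specific + nonspecific when both compete
        target = self._arr(0.012, 2000, seed=61)
        dark = self._arr(0.002, 2000, seed=62)
        out = kin.nonspecific_correction(target, dark, BOOT)
        assert abs(out["corrected_rate"] - 0.010) < 3 * out["se"]

    def test_dark_dominating_floors_at_zero(self):
        target = self._arr(0.002, 500, seed=63)
        dark = self._arr(0.02, 500, seed=64)
        out = kin.nonspecific_correction(target, dark, BOOT)
        assert out["corrected_rate"] == 0.0
        assert out["floored"]

    def test_requires_dark_sites(self):
        with pytest.raises(kin.KineticsError):
            kin.nonspecific_correction(self._arr(0.01, 10, seed=65),
                                       pd.DataFrame(), BOOT)


class TestMergeReplicates:
    def _exp(self, n, seed):
        rng = np.random.default_rng(seed)
        return {"arrivals": pd.DataFrame({
                    "site_id": range(n),
                    "arrival_s": rng.exponential(10.0, n),
                    "censored": False}),
                "concentration_M": 1e-10, "frame_interval_s": 0.1}

    def test_self_merge_doubles_n_keeps_rate(self):
        e = self._exp(200, seed=66)
        single = kin.estimate_kon(e["arrivals"], 1e-10, BOOT)
        merged = kin.merge_replicates([e, e], BOOT)
        assert merged.n_molecules == 400
        assert merged.k_on == pytest.approx(single.k_on, rel=1e-9)

    def test_pooled_se_below_single_replicate_se(self):
        reps = [self._exp(200, seed=s) for s in (67, 68, 69)]
        singles = [kin.estimate_kon(r["arrivals"], 1e-10, BOOT) for r in reps]
        merged = kin.merge_replicates(reps, BOOT)
        assert merged.se_kon < min(s.se_kon for s in singles)

    def test_empty_list_rejected(self):
        with pytest.raises(kin.KineticsError):
            kin.merge_replicates([])

    def test_unit_mismatch_rejected(self):
        a, b = self._exp(10, 70), self._exp(10, 71)
        b["concentration_M"] = 2e-10
        with pytest.raises(kin.KineticsError, match="concentration"):
            kin.merge_replicates([a, b])
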