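"""End-to-end orchestration with a scripted, reproducible configuration.

``run_pipeline`` executes calibrate -> register -> drift -> detect ->
localize -> colocalize -> kinetics (-> MGHMM when a K range is set) from a
single YAML-serializable :class:`RunConfig`, writing every intermediate
artifact, a structured log, and a frozen copy of the configuration into
the run directory, so an identical config and seed reproduce identical
outputs.  ``merge_runs`` pools completed runs into one kinetic estimate
with provenance.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import colocalization as coloc
from . import detection as det
from . import kinetics as kin
from . import localization as loc
from . import vbhmm
from .stacks import MovieStack


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All user-defined parameters of one experiment analysis."""

    # inputs
    gain_stacks: list[str] = field(default_factory=list)
    dark_stack: str = ""
    beads_ch1_csv: str = ""
    beads_ch2_csv: str = ""
    target_stack: str = ""
    binder_stack: str = ""
    # metadata
    pixel_size_nm: float = 160.0
    frame_interval_s: float = 0.1
    concentration_M: float = 1e-10
    seed: int = 0
    n_dark_sites: int = 50
    # stage parameters
    detection: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    hmm_k_range: list[int] = field(default_factory=list)
    hmm_priors: dict = field(default_factory=dict)
    hmm_restarts: int = 2

    def detection_params(self) -> det.DetectionParams:
        return det.DetectionParams(pixel_size_nm=self.pixel_size_nm,
                                   **self.detection)

    def event_criteria(self) -> coloc.EventCriteria:
        return coloc.EventCriteria(**self.events)

    def bootstrap_config(self) -> kin.BootstrapConfig:
        d = dict(self.bootstrap)
        d.setdefault("seed", self.seed)
        return kin.BootstrapConfig(**d)

    def validate(self) -> None:
        for name in ("dark_stack", "target_stack", "binder_stack"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigError(f"{name} not found: {path}")
        for path in self.gain_stacks:
            if not Path(path).exists():
                raise ConfigError(f"gain stack not found: {path}")
        for name in ("beads_ch1_csv", "beads_ch2_csv"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigError(f"{name} not found: {path}")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ConfigError("pixel size and frame interval must be positive")
        if self.concentration_M <= 0:
            raise ConfigError("binder concentration must be positive")
        # construct parameter objects so range errors surface before running
        self.detection_params()
        self.event_criteria()
        self.bootstrap_config()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: RunConfig, run_dir) -> dict:
    """Execute every configured stage; return the results dict.

    Artifacts written: ``config.yaml`` (frozen copy), ``calibration.json``,
    ``drift.csv``, ``sites.csv``, ``traces.csv``, ``events.csv``,
    ``arrivals.csv``, ``kinetics.json``, ``hmm.json`` (if enabled) and a
    per-stage ``log.txt``.  A stage failure halts the run with the stage
    name; artifacts of completed stages are retained.
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    log_lines: list[str] = []
    t_start = time.time()

    def log(stage: str, msg: str) -> None:
        line = f"[{time.time() - t_start:8.2f}s] {stage}: {msg}"
        log_lines.append(line)
        (run_dir / "log.txt").write_text("\n".join(log_lines) + "\n")

    results: dict = {}
    stage = "calibrate"
    try:
        # --- gain -----------------------------------------------------
        stacks = [MovieStack.load_tiff(p) for p in config.gain_stacks]
        dark = MovieStack.load_tiff(config.dark_stack)
        camcal = cal.estimate_gain(stacks, dark)
        results["calibration"] = camcal
        log(stage, f"gain={camcal.gain:.3f} counts/photon, "
                   f"offset={camcal.offset:.1f}, R2={camcal.r_squared:.4f}")

        # --- registration ---------------------------------------------
        stage = "register"
        channel_map = None
        if config.beads_ch1_csv:
            b1 = pd.read_csv(config.beads_ch1_csv)[["x", "y"]].to_numpy()
            b2 = pd.read_csv(config.beads_ch2_csv)[["x", "y"]].to_numpy()
            channel_map = cal.fit_affine_map(b1, b2, matched=False)
            log(stage, f"affine RMS residual {channel_map.rms_residual:.4f} px")
        results["channel_map"] = channel_map
        with open(run_dir / "calibration.json", "w") as fh:
            json.dump({"gain": camcal.gain, "offset": camcal.offset,
                       "r_squared": camcal.r_squared,
                       "affine": channel_map.to_dict() if channel_map else None},
                      fh, indent=1)

        # --- load movies, convert to photons ---------------------------
        stage = "photon-convert"
        target = MovieStack.load_tiff(config.target_stack,
                                      frame_interval_s=config.frame_interval_s,
                                      channel="target")
        binder = MovieStack.load_tiff(config.binder_stack,
                                      frame_interval_s=config.frame_interval_s,
                                      channel="binder")
        target_ph = cal.counts_to_photons(target, camcal)
        binder_ph = cal.counts_to_photons(binder, camcal)

        # --- drift ------------------------------------------------------
        stage = "drift"
        drift = cal.estimate_drift(target_ph)
        pd.DataFrame({"frame": np.arange(len(drift)),
                      "dx_px": drift.dx, "dy_px": drift.dy}).to_csv(
            run_dir / "drift.csv", index=False)
        log(stage, f"max |drift| {np.max(np.hypot(drift.dx, drift.dy)):.3f} px")

        # --- detect -----------------------------------------------------
        stage = "detect"
        params = config.detection_params()
        candidates = det.glrt_detect(target_ph.frame(0), params)
        half = loc.default_window_halfsize(params.sigma_psf)
        fit_rows = []
        for _, c in candidates.iterrows():
            cut = loc.cut_window(target_ph.frame(0), c["x_ref"], c["y_ref"], half)
            if cut is None:
                fit_rows.append({"sigma_gf": np.inf, "circularity": 0.0})
                continue
            win, _, _ = cut
            f = loc.mle_fit(win, params.sigma_psf)
            fit_rows.append({"sigma_gf": f.sigma if f.converged else np.inf,
                             "circularity": det.compute_circularity(win)})
        sites = det.filter_sites(candidates, pd.DataFrame(fit_rows), params)
        accepted = sites[sites["accepted"]].copy()
        accepted["dark"] = False
        log(stage, f"{len(candidates)} candidates, {len(accepted)} accepted; "
                   "rejections: " +
            str(sites.loc[~sites["accepted"], "reason"].value_counts().to_dict()))
        darks = loc.dark_locations(
            accepted, target_ph.data.shape[1:], config.n_dark_sites,
            seed=config.seed,
            min_separation_px=4.0 * params.sigma_psf)
        all_sites = pd.concat([accepted, darks], ignore_index=True)
        sites.to_csv(run_dir / "sites.csv", index=False)

        # --- localize ---------------------------------------------------
        stage = "localize"
        traces = loc.extract_traces(binder_ph, all_sites, drift, channel_map,
                                    sigma_psf=params.sigma_psf)
        traces.to_csv(run_dir / "traces.csv", index=False)
        results["traces"] = traces
        log(stage, f"{traces['site_id'].nunique()} sites x "
                   f"{binder_ph.n_frames} frames fitted")

        # --- colocalize -------------------------------------------------
        stage = "colocalize"
        criteria = config.event_criteria()
        events = coloc.events_from_traces(traces, criteria,
                                          config.frame_interval_s)
        events.to_csv(run_dir / "events.csv", index=False)
        site_ids = traces["site_id"].unique()
        arrivals = coloc.first_events(events, site_ids, binder_ph.n_frames,
                                      config.frame_interval_s)
        arrivals = arrivals.merge(
            traces.groupby("site_id")["dark"].first().rename("dark_site"),
            left_on="site_id", right_index=True, how="left")
        arrivals["dark"] = arrivals.pop("dark_site").astype(bool)
        arrivals.to_csv(run_dir / "arrivals.csv", index=False)
        results["events"] = events
        results["arrivals"] = arrivals
        log(stage, f"{len(events)} events; "
                   f"{int(arrivals['censored'].sum())} sites censored")

        # --- kinetics ---------------------------------------------------
        stage = "kinetics"
        boot = config.bootstrap_config()
        target_arr = arrivals[~arrivals["dark"]]
        dark_arr = arrivals[arrivals["dark"]]
        est = kin.estimate_kon(target_arr, config.concentration_M, boot)
        dwells = target_arr.dropna(subset=["dwell_s"])
        if len(dwells):
            koff = kin.estimate_koff(target_arr, boot=boot)
            est.k_off, est.se_koff = koff.k_off, koff.se_koff
            est.photobleach_limited = koff.photobleach_limited
        if len(dark_arr):
            corr = kin.nonspecific_correction(target_arr, dark_arr, boot)
            est.extra["nonspecific"] = {k: v for k, v in corr.items()
                                        if k != "bootstrap_rates"}
        results["kinetics"] = est
        payload = est.to_dict()
        payload["nonspecific"] = est.extra.get("nonspecific")
        with open(run_dir / "kinetics.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        log(stage, f"k_on={est.k_on:.3g}/M/s (SE {est.se_kon:.2g}), "
                   f"k_off={est.k_off:.3g}/s, n={est.n_molecules}")

        # --- MGHMM ------------------------------------------------------
        if config.hmm_k_range:
            stage = "hmm"
            obs = []
            for sid, tr in traces[~traces["dark"]].groupby("site_id"):
                t = tr.sort_values("frame")
                obs.append(t[["I_gf", "bg_est"]].to_numpy(dtype=float))
            priors = vbhmm.MGHMMPriors.from_dict(config.hmm_priors) \
                if config.hmm_priors else vbhmm.estimate_priors_from_traces(
                    traces, events[~events["dark"]])
            k_sel, table = vbhmm.select_order(
                obs, config.hmm_k_range, priors,
                restarts=config.hmm_restarts, seed=config.seed)
            post = table[k_sel]
            labels = vbhmm.decode_states(post, obs)
            occ = vbhmm.occupancy_rates(labels, config.frame_interval_s,
                                        config.concentration_M,
                                        seed=config.seed)
            results["hmm"] = {"selected_K": k_sel, "posterior": post,
                              "labels": labels, "occupancy_rates": occ}
            with open(run_dir / "hmm.json", "w") as fh:
                json.dump({"selected_K": k_sel,
                           "elbo_per_K": {str(k): (p.elbo if p else None)
                                          for k, p in table.items()},
                           "state_means": post.expected_means().tolist(),
                           "transition": post.expected_transition().tolist(),
                           "kon_ratio": occ["kon_ratio"],
                           "koff_ratio": occ["koff_ratio"]}, fh, indent=1)
            log(stage, f"selected K={k_sel}")
    except Exception as exc:
        log(stage, f"FAILED: {exc}")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    log("done", "pipeline complete")
    return results


def merge_runs(run_dirs: list, boot: kin.BootstrapConfig | None = None) -> dict:
    """Pool the arrival tables of completed runs into one kinetic estimate."""
    experiments = []
    for d in run_dirs:
        d = Path(d)
        cfg = RunConfig.from_yaml(d / "config.yaml")
        arrivals = pd.read_csv(d / "arrivals.csv")
        experiments.append({"arrivals": arrivals[~arrivals["dark"].astype(bool)],
                            "concentration_M": cfg.concentration_M,
                            "frame_interval_s": cfg.frame_interval_s})
    est = kin.merge_replicates(experiments, boot)
    return {"estimate": est, "parents": [str(d) for d in run_dirs]}
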