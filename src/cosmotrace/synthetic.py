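"""Synthetic data with recorded ground truth.

Generates every input the pipeline consumes — gain-calibration stacks,
two-channel bead fields, drifting binding movies, and multivariate-Gaussian
HMM observation traces — so the full analysis chain can be exercised and
validated against known truth without laboratory data.

The camera model is a scaled-Poisson EMCCD:

    counts = offset + gain * Poisson(lambda) + Normal(0, read_noise_sd)

which reproduces the linear mean-variance relation the gain calibration
exploits (``Var = gain * (mean - offset) + gain^2 * lambda_excess`` terms of
the full electron-multiplying cascade are not modelled; the pipeline only
consumes the linear relation).  Spots are rendered with the same
pixel-integrated Gaussian used by the localizer; drift moves the spot
centres in scene space rather than resampling images, so ground-truth
positions stay exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import AffineMap
from .psf import render_scene_frame
from .stacks import MovieStack


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CameraModel:
    """Scaled-Poisson EMCCD forward model (counts per photon, offset, read noise)."""

    gain: float = 30.0            # counts per photon
    offset: float = 100.0         # counts
    read_noise_sd: float = 0.0    # counts

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise SimulationError("camera gain must be positive")
        if self.offset < 0 or self.read_noise_sd < 0:
            raise SimulationError("offset and read noise must be nonnegative")

    def expose(self, photon_image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Raw counts for one frame of expected photons/pixel."""
        lam = np.clip(np.asarray(photon_image, dtype=float), 0.0, None)
        counts = self.offset + self.gain * rng.poisson(lam)
        if self.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, self.read_noise_sd, size=lam.shape)
        return counts.astype(float)


@dataclass
class Scene:
    """Static description of a field of view.

    ``spots`` rows are ``(x, y, photons_per_frame, sigma_psf)`` in pixels and
    photons; ``background`` is photons/pixel/frame, scalar or an (H, W)
    field; ``drift`` is the per-frame cumulative (dx, dy) trajectory of the
    sample; ``channel_map`` sends channel-1 coordinates onto channel 2.
    """

    shape: tuple[int, int]
    spots: np.ndarray
    background: float | np.ndarray = 2.0
    drift: np.ndarray | None = None           # (n_frames, 2)
    channel_map: AffineMap = field(default_factory=AffineMap.identity)

    def __post_init__(self) -> None:
        self.spots = np.atleast_2d(np.asarray(self.spots, dtype=float))
        if self.spots.size and self.spots.shape[1] != 4:
            raise SimulationError("spots must be rows of (x, y, photons, sigma)")
        h, w = self.shape
        if self.spots.size:
            x, y = self.spots[:, 0], self.spots[:, 1]
            if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
                raise SimulationError("all spot centres must lie inside the field")
        if np.any(np.asarray(self.background) < 0):
            raise SimulationError("background must be nonnegative everywhere")

    def to_json(self, path) -> None:
        d = {"shape": list(self.shape),
             "spots": self.spots.tolist(),
             "background": (self.background.tolist()
                            if isinstance(self.background, np.ndarray)
                            else float(self.background)),
             "drift": None if self.drift is None else np.asarray(self.drift).tolist(),
             "channel_map": self.channel_map.to_dict()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class TraceGroundTruth:
    """Markov-chain occupancy model with multivariate-Gaussian observations.

    ``means[k]`` and ``covs[k]`` are the per-state observation mean vector
    (signal, background; photons) and covariance (photons^2);
    ``transition`` is the row-stochastic per-frame transition matrix.
    """

    transition: np.ndarray
    means: np.ndarray
    covs: np.ndarray
    initial: np.ndarray | None = None
    frame_interval_s: float = 0.1

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.transition.shape[0]
        if self.transition.shape != (k, k) or np.any(self.transition < 0) or \
                not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise SimulationError("transition matrix must be row-stochastic")
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.means.shape[0] != k:
            raise SimulationError("one mean vector per state required")
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 2:
            self.covs = np.repeat(self.covs[None], k, axis=0)
        if self.initial is None:
            self.initial = self.stationary()
        else:
            self.initial = np.asarray(self.initial, dtype=float)
            self.initial = self.initial / self.initial.sum()

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left Perron eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def two_site_truth(p_on: float = 0.01, p_off: float = 0.005,
                   signal_leak: float = 60.0, signal_per_complex: float = 330.0,
                   background_mean: float = 200.0, signal_sd: float = 80.0,
                   background_sd: float = 40.0, correlation: float = 0.2,
                   n_sites: int = 2, frame_interval_s: float = 0.1,
                   ) -> TraceGroundTruth:
    """Occupancy-level ground truth for a target with independent identical sites.

    Each of ``n_sites`` binding sites turns on with per-frame probability
    ``p_on`` and off with ``p_off``; the occupancy level (number of bound
    complexes) is itself Markov with binomial aggregate transitions.  The
    observation vector per frame is (signal, background): signal mean grows
    by ``signal_per_complex`` photons per bound complex over a
    ``signal_leak`` baseline.  These defaults are the packaged
    "supplementary-table-like" experimental conditions used throughout the
    recovery tests.
    """
    n = n_sites
    K = n + 1
    trans = np.zeros((K, K))
    for k in range(K):          # k bound, n-k free
        for j in range(K):
            # j_on sites newly bound, j_off newly released; net level j
            p = 0.0
            for j_off in range(0, k + 1):
                j_on = j - k + j_off
                if not 0 <= j_on <= n - k:
                    continue
                from math import comb
                p += (comb(k, j_off) * p_off**j_off * (1 - p_off)**(k - j_off)
                      * comb(n - k, j_on) * p_on**j_on * (1 - p_on)**(n - k - j_on))
            trans[k, j] = p
    trans /= trans.sum(axis=1, keepdims=True)
    means = np.array([[signal_leak + signal_per_complex * k, background_mean]
                      for k in range(K)])
    rho = correlation * signal_sd * background_sd
    cov = np.array([[signal_sd**2, rho], [rho, background_sd**2]])
    return TraceGroundTruth(trans, means, cov,
                            frame_interval_s=frame_interval_s)


def default_truth() -> TraceGroundTruth:
    """The packaged three-state (two-site) ground truth configuration."""
    return two_site_truth()


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_calibration_stacks(camera: CameraModel,
                                illumination_levels: list[float],
                                frames_per_level: int, shape: tuple[int, int],
                                seed: int) -> tuple[list[MovieStack], MovieStack]:
    """Uniform-illumination stacks plus a dark stack for gain calibration.

    One raw stack per photon level (Poisson photons scaled through the
    camera model) and a zero-illumination dark stack.  The canonical input
    cardinality is 100 frames per stack.
    """
    if frames_per_level < 2:
        raise SimulationError("need >= 2 frames per level")
    levels = [float(v) for v in illumination_levels]
    if len(levels) < 1 or len(set(levels)) != len(levels):
        raise SimulationError("illumination levels must be distinct, >= 1 level")
    rng = np.random.default_rng(seed)
    h, w = shape
    stacks = []
    for lam in levels:
        frames = np.stack([camera.expose(np.full((h, w), lam), rng)
                           for _ in range(frames_per_level)])
        stacks.append(MovieStack(frames, units="counts",
                                 meta={"illumination_photons": lam}))
    dark_frames = np.stack([camera.expose(np.zeros((h, w)), rng)
                            for _ in range(frames_per_level)])
    dark = MovieStack(dark_frames, units="counts", meta={"illumination_photons": 0.0})
    return stacks, dark


def simulate_bead_field(n_beads: int, channel_map: AffineMap,
                        noise_sd: float, seed: int,
                        shape: tuple[int, int] = (128, 128),
                        photons: float = 2000.0, sigma: float = 1.3,
                        background: float = 5.0, render: bool = False,
                        ) -> dict:
    """Paired bead coordinates (and optionally rendered images) in two channels.

    Channel-2 coordinates are ``channel_map`` applied to channel-1
    coordinates plus isotropic Gaussian jitter of ``noise_sd`` pixels.
    Returns a dict with ``coords_ch1``, ``coords_ch2`` and, if ``render``,
    single-frame expected-photon images per channel.
    """
    if n_beads < 3:
        raise SimulationError("affine registration needs >= 3 beads")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 8.0
    coords1 = np.column_stack([rng.uniform(margin, w - margin, n_beads),
                               rng.uniform(margin, h - margin, n_beads)])
    # reject (near-)collinear draws: affine would be underdetermined
    for _ in range(100):
        centred = coords1 - coords1.mean(axis=0)
        if np.linalg.svd(centred, compute_uv=False)[-1] > 1e-6:
            break
        coords1 = np.column_stack([rng.uniform(margin, w - margin, n_beads),
                                   rng.uniform(margin, h - margin, n_beads)])
    coords2 = channel_map.apply(coords1)
    if noise_sd > 0:
        coords2 = coords2 + rng.normal(0.0, noise_sd, size=coords2.shape)
    out = {"coords_ch1": coords1, "coords_ch2": coords2}
    if render:
        out["image_ch1"] = render_scene_frame(
            shape, [(x, y, photons, sigma) for x, y in coords1], background)
        out["image_ch2"] = render_scene_frame(
            shape, [(x, y, photons, sigma) for x, y in coords2], background)
    return out


def simulate_state_sequences(truth: TraceGroundTruth, n_traces: int,
                             n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """(n_traces, n_frames) integer state sequences from the Markov chain."""
    K = truth.n_states
    states = np.empty((n_traces, n_frames), dtype=np.int64)
    cum_init = np.cumsum(truth.initial)
    cum_trans = np.cumsum(truth.transition, axis=1)
    u = rng.random((n_traces, n_frames))
    states[:, 0] = np.searchsorted(cum_init, u[:, 0])
    for t in range(1, n_frames):
        rows = cum_trans[states[:, t - 1]]
        states[:, t] = (u[:, t, None] > rows).sum(axis=1)
    return np.clip(states, 0, K - 1)


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD covariance (zero matrices allowed)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_traces(truth: TraceGroundTruth, n_traces: int, n_frames: int,
                    seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """MGHMM observation traces plus their hidden state sequences.

    Returns a table with columns ``trace, frame, signal, background`` (one
    row per frame, ``n_traces * n_frames`` rows in total) and the
    ``(n_traces, n_frames)`` ground-truth state array.
    """
    if n_traces < 1 or n_frames < 1:
        raise SimulationError("need >= 1 trace and >= 1 frame")
    rng = np.random.default_rng(seed)
    states = simulate_state_sequences(truth, n_traces, n_frames, rng)
    D = truth.n_dims
    chols = np.stack([_psd_sqrt(c) for c in truth.covs])
    z = rng.standard_normal((n_traces, n_frames, D))
    obs = truth.means[states] + np.einsum("ntij,ntj->nti", chols[states], z)
    idx_trace = np.repeat(np.arange(n_traces), n_frames)
    idx_frame = np.tile(np.arange(n_frames), n_traces)
    table = pd.DataFrame({"trace": idx_trace, "frame": idx_frame,
                          "signal": obs[:, :, 0].ravel(),
                          "background": obs[:, :, 1].ravel()
                          if D > 1 else np.zeros(n_traces * n_frames)})
    return table, states


def bootstrap_subsets(table: pd.DataFrame, sizes: list[int],
                      seed: int) -> list[pd.DataFrame]:
    """Bootstrap sub-datasets at trace granularity.

    Whole traces are resampled with replacement and concatenated until at
    least the requested number of data points is reached, then truncated to
    the exact size.  Each size must not exceed the parent size.
    """
    n_total = len(table)
    rng = np.random.default_rng(seed)
    traces = table["trace"].unique()
    by_trace = {t: g for t, g in table.groupby("trace")}
    out = []
    for size in sizes:
        if size <= 0:
            raise SimulationError("subset size must be positive")
        if size > n_total:
            raise SimulationError(f"subset size {size} exceeds parent {n_total}")
        parts, count = [], 0
        while count < size:
            t = traces[rng.integers(len(traces))]
            g = by_trace[t]
            parts.append(g)
            count += len(g)
        sub = pd.concat(parts, ignore_index=True).iloc[:size].copy()
        # relabel so each resampled block is its own trace
        block = np.concatenate([np.full(len(p), i) for i, p in enumerate(parts)])
        sub["trace"] = block[:size]
        out.append(sub)
    return out


def simulate_binding_movie(scene: Scene, occupancy: np.ndarray | None,
                           camera: CameraModel, n_frames: int, seed: int,
                           truth: TraceGroundTruth | None = None,
                           frame_interval_s: float = 0.1,
                           ) -> dict:
    """Two-channel raw movie of binders arriving at fixed target sites.

    Channel 1 (target) shows every scene spot in all frames; channel 2
    (binder) shows a spot only in frames where that site's occupancy state
    is bound (state > 0), with intensity ``photons * state``.  ``occupancy``
    is an ``(n_spots, n_frames)`` integer state array (``None`` means always
    bound, a static field).  Drift from the scene trajectory moves every
    spot centre identically.  Returns the two stacks plus ground-truth
    tables (per spot-frame positions and states).
    """
    rng = np.random.default_rng(seed)
    h, w = scene.shape
    n_spots = len(scene.spots) if scene.spots.size else 0
    drift = scene.drift
    if drift is None:
        drift = np.zeros((n_frames, 2))
    drift = np.asarray(drift, dtype=float)
    if len(drift) != n_frames:
        raise SimulationError("drift trajectory length must equal n_frames")
    if occupancy is not None:
        occupancy = np.asarray(occupancy)
        if occupancy.shape != (n_spots, n_frames):
            raise SimulationError("occupancy must be (n_spots, n_frames)")

    frames1 = np.empty((n_frames, h, w))
    frames2 = np.empty((n_frames, h, w))
    truth_rows = []
    for t in range(n_frames):
        dx, dy = drift[t]
        spots1, spots2 = [], []
        for i in range(n_spots):
            x, y, photons, sigma = scene.spots[i]
            xt, yt = x + dx, y + dy
            spots1.append((xt, yt, photons, sigma))
            state = 1 if occupancy is None else int(occupancy[i, t])
            x2, y2 = scene.channel_map.apply([xt, yt])[0]
            if state > 0:
                spots2.append((x2, y2, photons * state, sigma))
            truth_rows.append({"spot": i, "frame": t, "x": xt, "y": yt,
                               "x_ch2": x2, "y_ch2": y2, "state": state})
        frames1[t] = camera.expose(
            render_scene_frame((h, w), spots1, scene.background), rng)
        frames2[t] = camera.expose(
            render_scene_frame((h, w), spots2, scene.background), rng)

    truth_table = pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(
        columns=["spot", "frame", "x", "y", "x_ch2", "y_ch2", "state"])
    return {
        "target": MovieStack(frames1, units="counts",
                             frame_interval_s=frame_interval_s, channel="target"),
        "binder": MovieStack(frames2, units="counts",
                             frame_interval_s=frame_interval_s, channel="binder"),
        "truth": truth_table,
        "drift": drift,
    }
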