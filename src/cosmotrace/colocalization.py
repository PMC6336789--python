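"""Per-frame bound/unbound scoring and binding-event assembly.

A binder-channel frame at a target site counts as *bound* when all four
co-localization criteria hold simultaneously:

1. fitted spot intensity ``I_gf`` above a minimum photon count
   (default 150 photons),
2. signal-to-background ratio above a minimum (default 1), the background
   integrated over the fitted spot footprint ``2 pi sigma_gf^2 * bg_est``,
3. fitted position within a maximum distance of the (drift-corrected)
   target site (default 1 pixel),
4. fitted width ``sigma_gf`` at most a maximum (default 4.6 pixels).

Boolean frame sequences become events by closing gaps of at most
``gap_close`` frames *first* (bridging fluorophore blinking), then dropping
runs shorter than ``min_duration`` frames (non-specific flashes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EventCriteria:
    """Thresholds for frame scoring and event assembly (paper-default values)."""

    min_intensity_photons: float = 150.0
    min_sbr: float = 1.0
    max_distance_px: float = 1.0
    max_sigma_px: float = 4.6
    min_duration_frames: int = 2
    gap_close_frames: int = 2

    def __post_init__(self) -> None:
        if min(self.min_intensity_photons, self.min_sbr,
               self.max_distance_px, self.max_sigma_px) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_duration_frames < 0 or self.gap_close_frames < 0:
            raise ValueError("durations are nonnegative integers")


def score_frames(trace: pd.DataFrame, criteria: EventCriteria) -> np.ndarray:
    """Boolean bound/unbound per frame for one site's trace.

    ``trace`` rows (one per frame, sorted by frame) need
    ``I_gf, bg_est, sigma_gf, x_est, y_est, x_pred, y_pred, converged``;
    non-converged frames are unbound.
    """
    t = trace.sort_values("frame")
    dist = np.hypot(t["x_est"] - t["x_pred"], t["y_est"] - t["y_pred"])
    footprint = 2.0 * np.pi * t["sigma_gf"] ** 2 * t["bg_est"]
    sbr = t["I_gf"] / footprint.clip(lower=1e-12)
    bound = (
        t["converged"].to_numpy(dtype=bool)
        & (t["I_gf"].to_numpy() > criteria.min_intensity_photons)
        & (sbr.to_numpy() > criteria.min_sbr)
        & (dist.to_numpy() < criteria.max_distance_px)
        & (t["sigma_gf"].to_numpy() <= criteria.max_sigma_px)
    )
    return bound


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) indices of True runs."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def assemble_events(bound: np.ndarray, criteria: EventCriteria,
                    frame_interval_s: float, site_id: int = 0,
                    dark: bool = False,
                    intensities: np.ndarray | None = None) -> pd.DataFrame:
    """Bound-frame mask -> event table, gap closing before duration filtering.

    Gaps of at most ``gap_close_frames`` unbound frames between bound runs
    are bridged first; runs still shorter than ``min_duration_frames`` are
    then discarded.  Event duration is ``(end - start + 1) * frame
    interval`` seconds.
    """
    mask = np.asarray(bound, dtype=bool).copy()
    runs = _runs(mask)
    for (s1, e1), (s2, _) in zip(runs[:-1], runs[1:]):
        if s2 - e1 - 1 <= criteria.gap_close_frames:
            mask[e1 + 1:s2] = True
    rows = []
    for start, end in _runs(mask):
        if end - start + 1 < criteria.min_duration_frames:
            continue
        mean_i = np.nan
        if intensities is not None:
            mean_i = float(np.nanmean(np.asarray(intensities)[start:end + 1]))
        rows.append({"site_id": site_id, "start_frame": int(start),
                     "end_frame": int(end),
                     "duration_s": (end - start + 1) * frame_interval_s,
                     "mean_photons": mean_i, "first_event": False,
                     "dark": dark})
    events = pd.DataFrame(rows, columns=["site_id", "start_frame", "end_frame",
                                         "duration_s", "mean_photons",
                                         "first_event", "dark"])
    if len(events):
        events.loc[events.index[0], "first_event"] = True
    return events


def events_from_traces(traces: pd.DataFrame, criteria: EventCriteria,
                       frame_interval_s: float) -> pd.DataFrame:
    """Score and assemble events for every site in a trace table."""
    parts = []
    for site_id, trace in traces.groupby("site_id"):
        bound = score_frames(trace, criteria)
        ordered = trace.sort_values("frame")
        parts.append(assemble_events(
            bound, criteria, frame_interval_s, site_id=site_id,
            dark=bool(ordered["dark"].iloc[0]) if "dark" in ordered else False,
            intensities=ordered["I_gf"].to_numpy()))
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=["site_id", "start_frame", "end_frame",
                                     "duration_s", "mean_photons",
                                     "first_event", "dark"])
    return pd.concat(parts, ignore_index=True)


def first_events(events: pd.DataFrame, site_ids, n_frames: int,
                 frame_interval_s: float) -> pd.DataFrame:
    """Arrival/dwell table from the first binding event at each site.

    Only the first event per site is used (later events may involve
    photobleached molecules).  Sites with no event contribute a
    right-censored record with the full movie duration as the censoring
    time.  Columns: ``site_id, arrival_s, dwell_s, censored, dark``.
    """
    movie_s = n_frames * frame_interval_s
    rows = []
    for site_id in site_ids:
        ev = events[events["site_id"] == site_id].sort_values("start_frame")
        dark = bool(ev["dark"].iloc[0]) if len(ev) else False
        if len(ev) == 0:
            rows.append({"site_id": site_id, "arrival_s": movie_s,
                         "dwell_s": np.nan, "censored": True,
                         "dwell_censored": False, "dark": dark})
            continue
        first = ev.iloc[0]
        dwell_censored = bool(first["end_frame"] >= n_frames - 1)
        rows.append({"site_id": site_id,
                     "arrival_s": first["start_frame"] * frame_interval_s,
                     "dwell_s": float(first["duration_s"]),
                     "censored": False, "dwell_censored": dwell_censored,
                     "dark": dark})
    table = pd.DataFrame(rows, columns=["site_id", "arrival_s", "dwell_s",
                                        "censored", "dwell_censored", "dark"])
    table["dwell_censored"] = table["dwell_censored"].astype(bool)
    return table


def rastergram(events: pd.DataFrame, site_ids, n_frames: int) -> np.ndarray:
    """Site x frame occupancy matrix, rows sorted by first-event arrival.

    Sites that never bind sort last; arrival ties break stably by site id.
    """
    site_ids = list(site_ids)
    arrivals = {}
    for sid in site_ids:
        ev = events[events["site_id"] == sid]
        arrivals[sid] = int(ev["start_frame"].min()) if len(ev) else n_frames
    order = sorted(site_ids, key=lambda s: (arrivals[s], s))
    mat = np.zeros((len(order), n_frames), dtype=bool)
    for row, sid in enumerate(order):
        for _, ev in events[events["site_id"] == sid].iterrows():
            mat[row, int(ev["start_frame"]):int(ev["end_frame"]) + 1] = True
    return mat
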