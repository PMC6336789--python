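"""Maximum-likelihood spot fitting with theoretical precision bounds.

Each candidate window is fitted with the pixel-integrated 2-D Gaussian +
flat background model under the Poisson likelihood

    ll(theta) = sum_i [ n_i log mu_i(theta) - mu_i(theta) ],
    mu_i = bg + I * Ex_i(x, sigma) * Ey_i(y, sigma),

by damped Fisher scoring with analytic derivatives.  The inverse Fisher
information at the optimum is the Cramér–Rao lower bound (CRLB), reported
as the per-parameter precision: for a photon-calibrated image this is the
best precision any unbiased estimator can achieve, so the fit is both the
estimate and its own quality control.

The heavy path is batched: ``fit_windows`` fits thousands of windows
simultaneously with vectorized linear-algebra updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import AffineMap, DriftTrack
from .psf import pixel_profile, pixel_profile_dc, pixel_profile_dsigma
from .stacks import MovieStack

_PARAMS = ("x", "y", "intensity", "background", "sigma")


@dataclass
class LocalizationFit:
    """Converged (or sentinel) per-frame fit of one spot window.

    Positions in window pixel coordinates unless stated otherwise;
    intensity is integrated spot photons, background photons/pixel.
    """

    x: float
    y: float
    intensity: float
    background: float
    sigma: float
    crlb_x: float
    crlb_y: float
    crlb_intensity: float
    crlb_background: float
    crlb_sigma: float
    log_likelihood: float
    converged: bool
    iterations: int
    reason: str = ""


def default_window_halfsize(sigma_psf: float) -> int:
    """Half-size capturing >99% of the spot flux: ceil(3 sigma)."""
    return int(np.ceil(3.0 * sigma_psf))


def _model_and_derivs(params: np.ndarray, cols: np.ndarray, rows: np.ndarray,
                      fit_sigma: bool):
    """Expected image and d(mu)/d(theta) for a batch of windows.

    ``params`` is (N, 5) = (x, y, I, bg, sigma); returns mu (N, W, W) and
    derivs (N, P, W, W) with P = 5 or 4.
    """
    x, y, inten, bg, sig = (params[:, i][:, None] for i in range(5))
    ex = pixel_profile(cols[None, :], x, sig)            # (N, W)
    ey = pixel_profile(rows[None, :], y, sig)
    dex = pixel_profile_dc(cols[None, :], x, sig)
    dey = pixel_profile_dc(rows[None, :], y, sig)
    outer = ey[:, :, None] * ex[:, None, :]              # (N, W, W)
    mu = bg[:, :, None] + inten[:, :, None] * outer
    n = params.shape[0]
    w = cols.size
    p = 5 if fit_sigma else 4
    derivs = np.empty((n, p, w, w))
    derivs[:, 0] = inten[:, :, None] * ey[:, :, None] * dex[:, None, :]   # d/dx
    derivs[:, 1] = inten[:, :, None] * dey[:, :, None] * ex[:, None, :]   # d/dy
    derivs[:, 2] = outer                                                  # d/dI
    derivs[:, 3] = 1.0                                                    # d/dbg
    if fit_sigma:
        dsx = pixel_profile_dsigma(cols[None, :], x, sig)
        dsy = pixel_profile_dsigma(rows[None, :], y, sig)
        derivs[:, 4] = inten[:, :, None] * (dsy[:, :, None] * ex[:, None, :]
                                            + ey[:, :, None] * dsx[:, None, :])
    return mu, derivs


def _loglik(data: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.clip(mu, 1e-12, None)
    return np.sum(data * np.log(mu) - mu, axis=(-2, -1))


def initial_guess(windows: np.ndarray, sigma_psf: float) -> np.ndarray:
    """Centroid-of-window initialization (N, 5)."""
    windows = np.atleast_3d(windows)
    n, h, w = windows.shape
    edge = np.concatenate([windows[:, 0, :], windows[:, -1, :],
                           windows[:, :, 0], windows[:, :, -1]], axis=1)
    bg0 = np.clip(np.median(edge, axis=1), 1e-3, None)
    resid = np.clip(windows - bg0[:, None, None], 0.0, None)
    tot = resid.sum(axis=(1, 2))
    safe = np.clip(tot, 1e-9, None)
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)
    x0 = (resid.sum(axis=1) * cols).sum(axis=1) / safe
    y0 = (resid.sum(axis=2) * rows).sum(axis=1) / safe
    x0 = np.where(tot > 0, x0, (w - 1) / 2.0)
    y0 = np.where(tot > 0, y0, (h - 1) / 2.0)
    i0 = np.clip(tot, 1.0, None)
    return np.column_stack([x0, y0, i0, bg0,
                            np.full(n, float(sigma_psf))])


def fit_windows(windows: np.ndarray, sigma_psf: float, fit_sigma: bool = True,
                init: np.ndarray | None = None, max_iter: int = 100,
                tol: float = 1e-6) -> dict[str, np.ndarray]:
    """Batched Poisson MLE of the integrated-Gaussian model.

    Parameters
    ----------
    windows
        ``(N, W, W)`` photon sub-images (or a single ``(W, W)`` window).
    sigma_psf
        Nominal PSF width in pixels; the initial (and, if ``fit_sigma`` is
        False, fixed) width.
    init
        Optional ``(N, 5)`` initial parameters (x, y, I, bg, sigma).

    Returns
    -------
    dict of arrays: fitted parameters, CRLBs, log-likelihood, convergence
    flag, iteration counts, and failure reasons.
    """
    windows = np.asarray(windows, dtype=float)
    single = windows.ndim == 2
    if single:
        windows = windows[None]
    n, h, w = windows.shape
    if h != w:
        raise ValueError("windows must be square")
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)

    if np.any(windows < 0):
        raise ValueError("windows must be photon-calibrated (nonnegative)")

    params = initial_guess(windows, sigma_psf) if init is None \
        else np.array(init, dtype=float, copy=True)
    reason = np.full(n, "", dtype=object)
    empty = windows.sum(axis=(1, 2)) <= 0
    reason[empty] = "empty window"
    active = ~empty

    p = 5 if fit_sigma else 4
    mu, _ = _model_and_derivs(params, cols, rows, fit_sigma)
    ll = _loglik(windows, mu)
    iterations = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)

    for it in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        sub = params[idx]
        mu, derivs = _model_and_derivs(sub, cols, rows, fit_sigma)
        mu_c = np.clip(mu, 1e-12, None)
        resid = windows[idx] / mu_c - 1.0
        grad = np.einsum("npij,nij->np", derivs, resid)
        fisher = np.einsum("npij,nqij,nij->npq", derivs, derivs, 1.0 / mu_c)
        fisher = fisher + 1e-9 * np.eye(p)
        try:
            step = np.linalg.solve(fisher, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(f, g, rcond=None)[0]
                             for f, g in zip(fisher, grad)])

        # backtracking: accept only likelihood-improving steps
        cur_ll = ll[idx]
        new_params = sub.copy()
        accepted = np.zeros(len(idx), dtype=bool)
        scale = np.ones(len(idx))
        for _ in range(12):
            todo = ~accepted
            if not todo.any():
                break
            trial = sub[todo].copy()
            trial[:, :p] = sub[todo, :p] + scale[todo, None] * step[todo]
            trial[:, 2] = np.clip(trial[:, 2], 1e-6, None)   # I >= 0
            trial[:, 3] = np.clip(trial[:, 3], 1e-9, None)   # bg >= 0
            trial[:, 4] = np.clip(trial[:, 4], 0.3, 2.0 * w)
            mu_t, _ = _model_and_derivs(trial, cols, rows, fit_sigma)
            ll_t = _loglik(windows[idx][todo], mu_t)
            ok = ll_t >= cur_ll[todo] - 1e-12
            sel = np.where(todo)[0][ok]
            new_params[sel] = trial[ok]
            cur_ll[sel] = ll_t[ok]
            accepted[sel] = True
            scale[~accepted] *= 0.5
        # windows where no improving step exists are at a (local) optimum
        stalled = ~accepted
        moved = np.max(np.abs(new_params[:, :p] - sub[:, :p]), axis=1)
        done = stalled | (moved < tol)
        params[idx] = new_params
        ll[idx] = cur_ll
        iterations[idx] += 1
        newly = idx[done]
        converged[newly] = True
        active[newly] = False

    # flag fits whose centre wandered out of the window
    out = (params[:, 0] < -1) | (params[:, 0] > w) | \
          (params[:, 1] < -1) | (params[:, 1] > w)
    bad = out & ~empty
    converged[bad] = False
    reason[bad] = "centre left window"
    converged[empty] = False
    still = ~converged & ~empty & (reason == "")
    reason[still] = "max iterations"

    # CRLB from the Fisher information at the optimum
    crlb = np.full((n, 5), np.nan)
    good = converged
    if good.any():
        mu, derivs = _model_and_derivs(params[good], cols, rows, fit_sigma)
        mu_c = np.clip(mu, 1e-12, None)
        fisher = np.einsum("npij,nqij,nij->npq", derivs, derivs, 1.0 / mu_c)
        for k, i in enumerate(np.where(good)[0]):
            try:
                cov = np.linalg.inv(fisher[k] + 1e-12 * np.eye(p))
                d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
                crlb[i, :p] = d
            except np.linalg.LinAlgError:
                converged[i] = False
                reason[i] = "singular information"

    result = {
        "x": params[:, 0], "y": params[:, 1],
        "intensity": params[:, 2], "background": params[:, 3],
        "sigma": params[:, 4],
        "crlb_x": crlb[:, 0], "crlb_y": crlb[:, 1],
        "crlb_intensity": crlb[:, 2], "crlb_background": crlb[:, 3],
        "crlb_sigma": crlb[:, 4] if fit_sigma else np.full(n, np.nan),
        "log_likelihood": ll, "converged": converged,
        "iterations": iterations, "reason": reason.astype(str),
    }
    if single:
        result = {k: v[0] for k, v in result.items()}
    return result


def mle_fit(window: np.ndarray, sigma_psf: float = 1.3,
            init: tuple | None = None, fit_sigma: bool = True) -> LocalizationFit:
    """Fit a single window; see :func:`fit_windows`."""
    init_arr = None if init is None else np.asarray(init, dtype=float)[None]
    r = fit_windows(np.asarray(window, dtype=float), sigma_psf,
                    fit_sigma=fit_sigma, init=init_arr)
    return LocalizationFit(
        x=float(r["x"]), y=float(r["y"]), intensity=float(r["intensity"]),
        background=float(r["background"]), sigma=float(r["sigma"]),
        crlb_x=float(r["crlb_x"]), crlb_y=float(r["crlb_y"]),
        crlb_intensity=float(r["crlb_intensity"]),
        crlb_background=float(r["crlb_background"]),
        crlb_sigma=float(r["crlb_sigma"]),
        log_likelihood=float(r["log_likelihood"]),
        converged=bool(r["converged"]), iterations=int(r["iterations"]),
        reason=str(r["reason"]))


def crlb_for_model(x: float, y: float, intensity: float, background: float,
                   sigma: float, window: int, fit_sigma: bool = True) -> dict:
    """Theoretical CRLB of the model parameters for a given true spot.

    Independent oracle for precision tests: computed from the Fisher
    information of the exact forward model, no data involved.
    """
    cols = np.arange(window, dtype=float)
    rows = np.arange(window, dtype=float)
    params = np.array([[x, y, intensity, background, sigma]])
    mu, derivs = _model_and_derivs(params, cols, rows, fit_sigma)
    p = derivs.shape[1]
    fisher = np.einsum("npij,nqij,nij->npq", derivs, derivs,
                       1.0 / np.clip(mu, 1e-12, None))[0]
    cov = np.linalg.inv(fisher)
    names = _PARAMS[:p]
    return {name: float(np.sqrt(cov[i, i])) for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# Trace extraction
# ---------------------------------------------------------------------------

def cut_window(frame: np.ndarray, cx: float, cy: float,
               half: int) -> tuple[np.ndarray, int, int] | None:
    """Square window of half-size ``half`` centred at the nearest pixel.

    Returns (window, x0, y0) or None when clipped by the field edge.
    """
    h, w = frame.shape
    ix, iy = int(round(cx)), int(round(cy))
    x0, x1 = ix - half, ix + half + 1
    y0, y1 = iy - half, iy + half + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return None
    return frame[y0:y1, x0:x1], x0, y0


def extract_traces(stack: MovieStack, sites: pd.DataFrame,
                   drift: DriftTrack | None = None,
                   channel_map: AffineMap | None = None,
                   sigma_psf: float = 1.3, fit_sigma: bool = True,
                   window_halfsize: int | None = None) -> pd.DataFrame:
    """Per-site, per-frame MLE fits in the (mapped, drift-corrected) windows.

    ``sites`` needs columns ``site_id, x_ref, y_ref`` (frame-0 reference
    coordinates in the reference channel).  ``channel_map`` sends reference-
    channel coordinates onto the coordinates of ``stack``'s channel (pass
    None when extracting from the reference channel itself).  For every
    frame the window is centred at the site position propagated through the
    drift track and the channel map; fits are returned in global stack
    coordinates, one row per site x frame (dense: non-converged frames
    carry sentinel values with ``converged=False``).  Sites whose window is
    ever clipped by the field edge are excluded and reported via the
    ``excluded`` attribute.
    """
    if stack.units != "photons":
        raise ValueError("extract_traces requires a photon-calibrated stack")
    half = window_halfsize if window_halfsize is not None \
        else default_window_halfsize(sigma_psf)
    n_frames = stack.n_frames
    if drift is None:
        drift = DriftTrack.zero(n_frames)

    def predicted(ref: np.ndarray, t: int) -> np.ndarray:
        pos = ref + drift.displacement(t)
        if channel_map is not None:
            pos = channel_map.apply(pos)[0]
        return pos

    rows = []
    excluded = []
    for _, site in sites.iterrows():
        ref = np.array([site["x_ref"], site["y_ref"]])
        wins, origins, frames_ok = [], [], []
        clipped = False
        for t in range(n_frames):
            pos = predicted(ref, t)
            cut = cut_window(stack.data[t], pos[0], pos[1], half)
            if cut is None:
                clipped = True
                break
            win, x0, y0 = cut
            wins.append(win)
            origins.append((x0, y0))
            frames_ok.append(t)
        if clipped:
            excluded.append({"site_id": site["site_id"],
                             "reason": "window clipped by field edge"})
            continue
        res = fit_windows(np.stack(wins), sigma_psf, fit_sigma=fit_sigma)
        for k, t in enumerate(frames_ok):
            x0, y0 = origins[k]
            pred = predicted(ref, t)
            rows.append({
                "site_id": site["site_id"], "frame": t,
                "x_est": res["x"][k] + x0, "y_est": res["y"][k] + y0,
                "bg_est": res["background"][k], "I_gf": res["intensity"][k],
                "sigma_gf": res["sigma"][k],
                "crlb_x": res["crlb_x"][k], "crlb_y": res["crlb_y"][k],
                "crlb_I": res["crlb_intensity"][k],
                "converged": bool(res["converged"][k]),
                "x_pred": pred[0], "y_pred": pred[1],
                "dark": bool(site.get("dark", False)),
            })
    traces = pd.DataFrame(rows)
    traces.attrs["excluded"] = excluded
    traces.attrs["frame_interval_s"] = stack.frame_interval_s
    traces.attrs["channel"] = stack.channel
    return traces


def dark_locations(sites: pd.DataFrame, shape: tuple[int, int], n_dark: int,
                   seed: int, min_separation_px: float = 3.0,
                   margin: float = 4.0) -> pd.DataFrame:
    """Pseudo-sites in target-free regions, controls for non-specific binding.

    Uniformly sampled positions at least ``min_separation_px`` from every
    real site and from each other; raises if the field cannot host
    ``n_dark`` such positions (reporting the count achieved).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    real = sites[["x_ref", "y_ref"]].to_numpy(dtype=float) if len(sites) \
        else np.empty((0, 2))
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * max(n_dark, 1)
    while len(placed) < n_dark and attempts < max_attempts:
        attempts += 1
        cand = np.array([rng.uniform(margin, w - margin),
                         rng.uniform(margin, h - margin)])
        pool = np.vstack([real] + [p[None] for p in placed]) if (len(real) or placed) \
            else np.empty((0, 2))
        if pool.size and np.min(np.linalg.norm(pool - cand, axis=1)) < min_separation_px:
            continue
        placed.append(cand)
    if len(placed) < n_dark:
        raise ValueError(
            f"insufficient empty area: placed {len(placed)} of {n_dark} dark sites")
    start = int(sites["site_id"].max()) + 1 if len(sites) else 0
    return pd.DataFrame({
        "site_id": np.arange(start, start + n_dark),
        "x_ref": [p[0] for p in placed], "y_ref": [p[1] for p in placed],
        "dark": True,
    })
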