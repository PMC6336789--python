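"""Camera and geometric calibration.

Three independent corrections turn raw two-channel camera stacks into a
common, photon-calibrated coordinate frame:

* **Gain/offset** — an EMCCD in the linear regime obeys
  ``Var[counts] = gain * (E[counts] - offset) + const`` for Poisson photon
  input, so the gain is the slope of the per-pixel temporal variance
  against the temporal mean across illumination levels, and the offset is
  the dark-frame mean.  Photon conversion is ``(counts - offset) / gain``.
* **Channel mapping** — an affine transform (rotation, scaling, shear,
  translation) fitted by least squares to matched bead positions imaged in
  both channels.
* **Drift** — lateral stage drift estimated from the cross-correlation of
  consecutive frames of the target channel, the immobilized targets acting
  as fiducial-free markers.  Coordinates are corrected; images are never
  resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .stacks import MovieStack


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Gain / offset
# ---------------------------------------------------------------------------

@dataclass
class CameraCalibration:
    """Gain/offset pair converting camera counts to photons."""

    gain: float                  # counts per photon
    offset: float                # counts
    gain_se: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    r_squared: float = np.nan

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise CalibrationError("camera gain must be positive")

    def to_photons(self, counts: np.ndarray) -> np.ndarray:
        return np.clip((np.asarray(counts, dtype=float) - self.offset) / self.gain,
                       0.0, None)


def estimate_gain(stacks: list[MovieStack], dark: MovieStack,
                  hot_pixel_fraction: float = 0.01) -> CameraCalibration:
    """Estimate EMCCD gain and offset from uniform-illumination stacks.

    Per-pixel temporal means and variances are pooled over all stacks and a
    least-squares line ``variance = gain * mean + intercept`` is fitted
    after discarding the ``hot_pixel_fraction`` highest-variance pixels of
    each level (hot pixels).  The offset is the dark-stack mean.

    Raises
    ------
    CalibrationError
        If fewer than two distinct illumination levels are provided
        ("insufficient dynamic range") or the fitted slope is not positive
        ("calibration failure").
    """
    if len(stacks) < 1:
        raise CalibrationError("need at least one illuminated stack")
    means, variances = [], []
    level_means = []
    for st in stacks:
        if st.n_frames < 2:
            raise CalibrationError("need >= 2 frames per level for a variance")
        m = st.data.mean(axis=0).ravel()
        v = st.data.var(axis=0, ddof=1).ravel()
        keep = v <= np.quantile(v, 1.0 - hot_pixel_fraction)
        means.append(m[keep])
        variances.append(v[keep])
        level_means.append(float(m.mean()))
    level_means.append(float(dark.data.mean()))
    means.append(dark.data.mean(axis=0).ravel())
    variances.append(dark.data.var(axis=0, ddof=1).ravel())

    spread = max(level_means) - min(level_means)
    if spread < 1e-9 or len(set(np.round(level_means, 6))) < 2:
        raise CalibrationError("insufficient dynamic range: all levels equal-mean")

    x = np.concatenate(means)
    y = np.concatenate(variances)
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise CalibrationError("calibration failure: non-positive variance slope")
    offset = float(dark.data.mean())
    return CameraCalibration(
        gain=float(res.slope), offset=offset,
        gain_se=float(res.stderr), intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
    )


def counts_to_photons(stack: MovieStack, cal: CameraCalibration) -> MovieStack:
    """Convert a raw stack to photon units, clipping below zero."""
    out = stack.with_data(cal.to_photons(stack.data), units="photons")
    return out


# ---------------------------------------------------------------------------
# Affine channel mapping
# ---------------------------------------------------------------------------

@dataclass
class AffineMap:
    """2-D affine transform ``y = A @ x + b`` between channel coordinates."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise CalibrationError("affine map is singular")

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return coords @ self.matrix.T + self.translation

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.matrix)
        return AffineMap(inv, -inv @ self.translation, self.rms_residual)

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(),
                "translation": self.translation.tolist(),
                "rms_residual": float(self.rms_residual)}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineMap":
        return cls(np.array(d["matrix"]), np.array(d["translation"]),
                   float(d.get("rms_residual", 0.0)))


def match_points(points_a: np.ndarray, points_b: np.ndarray,
                 max_dist: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbour correspondence after coarse prealignment.

    The median translation between the two clouds is removed before the
    KD-tree queries; pairs are kept only when each point is the other's
    nearest neighbour within ``max_dist`` pixels.
    """
    a = np.atleast_2d(points_a).astype(float)
    b = np.atleast_2d(points_b).astype(float)
    shift = np.median(b, axis=0) - np.median(a, axis=0)
    a_shifted = a + shift
    tree_b = cKDTree(b)
    tree_a = cKDTree(a_shifted)
    d_ab, j_ab = tree_b.query(a_shifted, distance_upper_bound=max_dist)
    _, i_ba = tree_a.query(b, distance_upper_bound=max_dist)
    ia, ib = [], []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if np.isfinite(d) and j < len(b) and i_ba[j] == i:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def fit_affine_map(points_ch1: np.ndarray, points_ch2: np.ndarray,
                   matched: bool = True) -> AffineMap:
    """Least-squares affine map sending channel-1 onto channel-2 coordinates.

    With ``matched=False`` correspondence is first established by mutual
    nearest neighbours (:func:`match_points`).  Requires at least three
    non-collinear pairs; the RMS of the mapped residuals is reported.
    """
    p1 = np.atleast_2d(points_ch1).astype(float)
    p2 = np.atleast_2d(points_ch2).astype(float)
    if not matched:
        ia, ib = match_points(p1, p2)
        p1, p2 = p1[ia], p2[ib]
    if p1.shape != p2.shape:
        raise CalibrationError("matched point sets must have equal length")
    if len(p1) < 3:
        raise CalibrationError("affine fit needs >= 3 matched pairs")
    design = np.column_stack([p1, np.ones(len(p1))])
    if np.linalg.matrix_rank(design) < 3:
        raise CalibrationError("rank-deficient: bead configuration is collinear")
    coef, *_ = np.linalg.lstsq(design, p2, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    resid = p2 - design @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineMap(matrix, translation, rms)


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------

@dataclass
class DriftTrack:
    """Cumulative lateral drift per frame, in pixels.

    ``dx[t], dy[t]`` is the apparent motion of the sample between frame 0
    and frame ``t``; frame 0 is the reference, so ``dx[0] = dy[0] = 0``.
    """

    dx: np.ndarray
    dy: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.uncertainty is None:
            self.uncertainty = np.zeros_like(self.dx)

    def __len__(self) -> int:
        return len(self.dx)

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTrack":
        return cls(np.zeros(n_frames), np.zeros(n_frames))

    def displacement(self, frame: int) -> np.ndarray:
        if not 0 <= frame < len(self.dx):
            raise IndexError(f"frame {frame} outside drift track")
        return np.array([self.dx[frame], self.dy[frame]])


def _parabolic_peak(cc: np.ndarray) -> tuple[float, float]:
    """Sub-pixel correlation peak by 3x3 parabolic interpolation."""
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    h, w = cc.shape

    def offset(fm, f0, fp):
        denom = fm - 2.0 * f0 + fp
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))

    dx = dy = 0.0
    if 0 < ix < w - 1:
        dx = offset(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    if 0 < iy < h - 1:
        dy = offset(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    return ix + dx, iy + dy


def _pair_shift(ref: np.ndarray, moving: np.ndarray,
                max_shift: int) -> tuple[float, float, float]:
    """Shift of ``moving`` relative to ``ref`` from the correlation peak.

    Returns (sx, sy, significance); significance is the peak height in
    units of the correlation-surface standard deviation.
    """
    a = ref - ref.mean()
    b = moving - moving.mean()
    cc = fftconvolve(b, a[::-1, ::-1], mode="same")
    h, w = cc.shape
    cy, cx = h // 2, w // 2
    window = cc[max(0, cy - max_shift): cy + max_shift + 1,
                max(0, cx - max_shift): cx + max_shift + 1]
    px, py = _parabolic_peak(window)
    sx = px + max(0, cx - max_shift) - cx
    sy = py + max(0, cy - max_shift) - cy
    sd = cc.std()
    signif = float((cc.max() - cc.mean()) / sd) if sd > 0 else 0.0
    return float(sx), float(sy), signif


def estimate_drift(stack: MovieStack, max_shift: int = 10,
                   min_significance: float = 5.0,
                   smooth_window: int = 0) -> DriftTrack:
    """Estimate cumulative lateral drift from consecutive-frame correlation.

    Each consecutive frame pair contributes a sub-pixel shift from the 3x3
    parabolic interpolation of its cross-correlation peak; shifts are
    cumulatively summed, anchored at frame 0.  Pairs whose correlation peak
    falls below ``min_significance`` standard deviations are held at the
    previous shift and flagged with infinite per-frame uncertainty.
    """
    if stack.n_frames < 2:
        raise CalibrationError("drift estimation needs >= 2 frames")
    n = stack.n_frames
    step_x = np.zeros(n)
    step_y = np.zeros(n)
    unc = np.zeros(n)
    for t in range(1, n):
        sx, sy, signif = _pair_shift(stack.data[t - 1], stack.data[t], max_shift)
        if signif < min_significance:
            step_x[t], step_y[t] = step_x[t - 1], step_y[t - 1]
            unc[t] = np.inf
        else:
            step_x[t], step_y[t] = sx, sy
            unc[t] = 1.0 / max(signif, 1e-12)
    dx = np.cumsum(step_x)
    dy = np.cumsum(step_y)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        dx = np.convolve(np.pad(dx, pad, mode="edge"), kernel, mode="same")[pad:pad + n]
        dy = np.convolve(np.pad(dy, pad, mode="edge"), kernel, mode="same")[pad:pad + n]
        dx -= dx[0]
        dy -= dy[0]
    return DriftTrack(dx, dy, unc)


def apply_corrections(coords: np.ndarray, frame: int, drift: DriftTrack,
                      channel_map: AffineMap | None = None) -> np.ndarray:
    """Map coordinates across channels, then express them in the frame-0 frame.

    The channel map (if given) is applied first; the drift displacement of
    ``frame`` is then subtracted, so the output coordinates are comparable
    to frame-0 reference positions.  Pure coordinate transform: images are
    never interpolated.
    """
    out = np.atleast_2d(np.asarray(coords, dtype=float))
    if channel_map is not None:
        out = channel_map.apply(out)
    out = out - drift.displacement(frame)
    return out


def unapply_corrections(coords: np.ndarray, frame: int, drift: DriftTrack,
                        channel_map: AffineMap | None = None) -> np.ndarray:
    """Inverse of :func:`apply_corrections` (reference -> observed frame)."""
    out = np.atleast_2d(np.asarray(coords, dtype=float)) + drift.displacement(frame)
    if channel_map is not None:
        out = channel_map.inverse().apply(out)
    return out
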