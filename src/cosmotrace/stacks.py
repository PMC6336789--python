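"""Image-stack container and TIFF I/O.

A :class:`MovieStack` is the time series of one camera channel, either in
raw camera counts or (after gain calibration) in photons.  Frames are
indexed ``stack.data[t, y, x]``; coordinates everywhere in the package are
0-based pixel indices with a spot at integer ``(x, y)`` centred in that
pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class MovieStack:
    """Calibrated or raw image time series for one channel.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, height, width)``.
    units
        ``"counts"`` for raw camera digital units, ``"photons"`` after
        gain conversion.
    frame_interval_s
        Acquisition interval between frames, in seconds.
    channel
        Free-form channel label (e.g. ``"target"``, ``"binder"``).
    """

    data: np.ndarray
    units: str = "counts"
    frame_interval_s: float = 0.1
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("MovieStack data must be (n_frames, H, W)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def with_data(self, data: np.ndarray, units: str | None = None) -> "MovieStack":
        return replace(self, data=data, units=units or self.units)

    def save_tiff(self, path) -> None:
        """Write as multi-page 16-bit unsigned TIFF (counts are rounded)."""
        arr = np.clip(np.rint(self.data), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, arr, photometric="minisblack")

    @classmethod
    def load_tiff(cls, path, units: str = "counts",
                  frame_interval_s: float = 0.1, channel: str = "") -> "MovieStack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return cls(arr.astype(np.float64), units=units,
                   frame_interval_s=frame_interval_s, channel=channel)
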