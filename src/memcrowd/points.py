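"""Planar point patterns in a rectangular observation window (nm units)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PointPattern:
    """A set of planar points inside a rectangular window.

    Parameters
    ----------
    points : ndarray, shape (N, 2)
        (x, y) coordinates in nanometres.
    window : (float, float)
        (width, height) of the observation window in nanometres; the window
        is the axis-aligned rectangle [0, width] x [0, height].
    channel : str
        Channel label of the maxima the pattern represents.
    border_flags : ndarray of bool, optional
        Per-point flag, e.g. maxima sitting on an ROI border.
    """

    points: np.ndarray
    window: tuple[float, float]
    channel: str = ""
    border_flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (N, 2)")
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValueError("window dimensions must be positive")
        eps = 1e-9 * max(w, h)
        if pts.size and (
            pts[:, 0].min() < -eps
            or pts[:, 1].min() < -eps
            or pts[:, 0].max() > w + eps
            or pts[:, 1].max() > h + eps
        ):
            raise ValueError("all points must lie inside the window")
        self.points = pts
        self.window = (float(w), float(h))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def area_um2(self) -> float:
        return self.window[0] * self.window[1] / 1e6

    @property
    def density_per_um2(self) -> float:
        """Point density in points per square micrometre."""
        return len(self) / self.area_um2

    def translated(self, dx: float, dy: float) -> "PointPattern":
        """Rigid translation; the window stays fixed, so points must remain inside."""
        return PointPattern(
            self.points + np.array([dx, dy]), self.window, self.channel
        )
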