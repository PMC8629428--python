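"""Membrane-sheet segmentation and per-sheet intensity extraction.

Glass-adhered membrane sheets imaged at epifluorescence scale are segmented
by the blur-and-threshold recipe: smooth the reference channel with a wide
Gaussian (sigma = 3 px by default) to define the sheet outlines, threshold
the smoothed frame (Otsu by default), label connected components, and
discard components below a minimum area.  The resulting binary mask is then
overlaid on the *raw* images of both channels to measure per-sheet mean
intensities, which feed the intensity-intensity regression stage.

Also implements the confocal plasma-membrane fraction arithmetic from three
nested ROIs (outer rim / inner rim / nucleus) of an equatorial cell section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imaging import Image2D, gaussian_blur


@dataclass
class SheetMask:
    """Labelled sheet segmentation: 0 = background, 1..n = sheet ids."""

    labels: np.ndarray
    pixel_size_nm: float
    blur_sigma_px: float
    threshold: float

    @property
    def n_sheets(self) -> int:
        return int(self.labels.max())

    @property
    def sheet_ids(self) -> np.ndarray:
        return np.arange(1, self.n_sheets + 1)

    def area_um2(self, sheet_id: int) -> float:
        n = int((self.labels == sheet_id).sum())
        return n * (self.pixel_size_nm / 1000.0) ** 2

    def touches_border(self, sheet_id: int) -> bool:
        m = self.labels == sheet_id
        return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())


@dataclass
class MembraneFractionInput:
    """Background-corrected integrated densities of three nested ROIs."""

    outer_rim: float
    inner_rim: float
    nucleus: float

    def __post_init__(self) -> None:
        if not (self.outer_rim >= self.inner_rim >= self.nucleus >= 0):
            raise ValueError(
                "integrated densities must satisfy outer_rim >= inner_rim >= nucleus >= 0"
            )


def segment_sheets(
    image: Image2D,
    sigma_px: float = 3.0,
    threshold_rule: str | float = "otsu",
    min_area_um2: float = 4.0,
) -> SheetMask:
    """Blur-and-threshold sheet segmentation.

    Parameters
    ----------
    image : Image2D
        The reference (GFP) epifluorescence channel.
    sigma_px : float
        Gaussian blur applied before thresholding to define sheet outlines.
    threshold_rule : "otsu" or float
        Otsu's method on the blurred frame, or a fixed absolute threshold.
    min_area_um2 : float
        Components smaller than this are discarded as debris.

    Sheets touching the frame border are kept (flag them downstream with
    :meth:`SheetMask.touches_border`).  If nothing survives, an empty mask is
    returned with a warning rather than an error.
    """
    blurred = gaussian_blur(image, sigma_px).pixels
    if threshold_rule == "otsu":
        if np.ptp(blurred) == 0:
            warnings.warn("flat image: no sheets segmented", stacklevel=2)
            return SheetMask(
                np.zeros(image.shape, dtype=np.int32),
                image.pixel_size_nm,
                sigma_px,
                float(blurred.flat[0]),
            )
        thr = float(threshold_otsu(blurred))
    else:
        thr = float(threshold_rule)
    binary = blurred > thr
    labels = cc_label(binary, connectivity=2)

    px_area_um2 = (image.pixel_size_nm / 1000.0) ** 2
    min_px = min_area_um2 / px_area_um2
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for region in regionprops(labels):
        if region.area >= min_px:
            out[labels == region.label] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("no membrane sheet above the minimum area", stacklevel=2)
    return SheetMask(out, image.pixel_size_nm, sigma_px, thr)


def sheet_intensity_table(
    raw_a: Image2D,
    raw_b: Image2D,
    mask: SheetMask,
    background_a: float = 0.0,
    background_b: float = 0.0,
) -> pd.DataFrame:
    """Per-sheet background-corrected mean intensities of both raw channels.

    Means are always measured on the raw pixels; the blurred frame is used
    for segmentation only.  Returns one row per sheet with columns
    ``sheet_id, area_um2, mean_a, mean_b, touches_border``.
    """
    if raw_a.shape != mask.labels.shape or raw_b.shape != mask.labels.shape:
        raise ValueError("image shapes do not match the sheet mask")
    rows = []
    for sid in mask.sheet_ids:
        sel = mask.labels == sid
        rows.append(
            {
                "sheet_id": int(sid),
                "area_um2": mask.area_um2(sid),
                "mean_a": float(raw_a.pixels[sel].mean()) - background_a,
                "mean_b": float(raw_b.pixels[sel].mean()) - background_b,
                "touches_border": mask.touches_border(sid),
            }
        )
    return pd.DataFrame(
        rows, columns=["sheet_id", "area_um2", "mean_a", "mean_b", "touches_border"]
    )


def plasma_membrane_fraction(inp: MembraneFractionInput) -> float:
    """Fraction of signal at the plasma membrane from nested-ROI densities.

    plasma membrane signal = outer rim - inner rim;
    cytoplasm signal = inner rim - nucleus;
    fraction = pm / (pm + cytoplasm).
    """
    pm = inp.outer_rim - inp.inner_rim
    cyto = inp.inner_rim - inp.nucleus
    total = pm + cyto
    if total <= 0:
        raise ValueError("plasma-membrane fraction undefined: pm + cytoplasm <= 0")
    return pm / total
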