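"""Pixel-level primitives shared by every analysis stage.

The image model is deliberately minimal: a 2-D grid of non-negative
intensities with a physical pixel size in nanometres and a free-text channel
label.  All statistics are computed in floating point regardless of the
integer depth of the input, and background correction never clips negative
pixels so that ROI means stay unbiased.

The two colocalization primitives implement the Pearson correlation
coefficient (PCC) over an ROI and its chance-overlap control, in which one
channel is rotated by 180 degrees ("flipped vertically and horizontally")
before the correlation is evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested on a constant channel."""


@dataclass
class Image2D:
    """A single-channel 2-D intensity image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Non-negative intensities in arbitrary units.  Stored as float64.
    pixel_size_nm : float
        Length of one pixel edge in nanometres (25 for STED-like imagery,
        266.67 for epifluorescence-like imagery).
    channel : str
        Free-text channel label, e.g. ``"stx"`` or ``"snap25"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D grid with >=1 row and column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.pixel_size_nm, self.channel)


@dataclass
class RegionOfInterest:
    """A boolean mask selecting the analyzed area of an :class:`Image2D`."""

    mask: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI selects no pixels")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @classmethod
    def full(cls, image: Image2D) -> "RegionOfInterest":
        return cls(np.ones(image.shape, dtype=bool), image.pixel_size_nm)

    @classmethod
    def from_rectangle(
        cls, image: Image2D, row0: int, row1: int, col0: int, col1: int
    ) -> "RegionOfInterest":
        mask = np.zeros(image.shape, dtype=bool)
        mask[row0:row1, col0:col1] = True
        return cls(mask, image.pixel_size_nm)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        """Area in square micrometres: pixel count times (pixel edge / 1000)^2."""
        return self.n_pixels * (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class IntensityStats:
    """Background-corrected ROI intensity statistics.

    ``rsdm`` (relative standard deviation of the mean) is the coefficient of
    variation of the ROI pixel intensities, sd/mean, and quantifies the
    degree of clustering of the stained protein: a uniform stain gives a low
    rSDM, a patchy one a high rSDM.  When the corrected mean is not positive
    the ratio is undefined and reported as NaN with ``rsdm_defined`` False.
    """

    mean: float
    sd: float
    background: float
    rsdm: float = field(init=False)
    rsdm_defined: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.mean > 0:
            self.rsdm = self.sd / self.mean
            self.rsdm_defined = True
        else:
            self.rsdm = math.nan
            self.rsdm_defined = False


def _check_congruent(image: Image2D, roi: RegionOfInterest) -> None:
    if image.shape != roi.mask.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match image shape {image.shape}"
        )


def gaussian_blur(image: Image2D, sigma_px: float) -> Image2D:
    """Gaussian smoothing with reflective boundary handling.

    ``sigma_px`` is in pixel units; 0 returns an identical copy.  Reflection
    at the borders conserves total intensity.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return image.copy()
    smoothed = ndimage.gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect")
    return Image2D(smoothed, image.pixel_size_nm, image.channel)


def roi_mean_intensity(
    image: Image2D,
    roi: RegionOfInterest,
    background: float = 0.0,
    subtract_background_for_rsdm: bool = True,
) -> IntensityStats:
    """Mean, SD and rSDM of the ROI pixels after scalar background subtraction.

    The sample (n-1) standard deviation is used.  Negative corrected pixels
    are retained.  With ``subtract_background_for_rsdm=False`` the rSDM is
    computed on raw (uncorrected) pixels while mean/sd stay corrected; the
    default subtracts, which is also what the corrected mean/sd imply.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    _check_congruent(image, roi)
    values = image.pixels[roi.mask]
    corrected = values - background
    mean = float(corrected.mean())
    sd = float(corrected.std(ddof=1)) if corrected.size > 1 else 0.0
    if subtract_background_for_rsdm:
        return IntensityStats(mean=mean, sd=sd, background=background)
    raw_mean = float(values.mean())
    stats = IntensityStats(mean=mean, sd=sd, background=background)
    if raw_mean > 0:
        stats.rsdm = sd / raw_mean
        stats.rsdm_defined = True
    return stats


def pcc(image_a: Image2D, image_b: Image2D, roi: RegionOfInterest) -> float:
    """Pearson correlation of paired pixel intensities inside the ROI."""
    _check_congruent(image_a, roi)
    _check_congruent(image_b, roi)
    a = image_a.pixels[roi.mask]
    b = image_b.pixels[roi.mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ZeroVarianceError("PCC undefined: a channel has zero variance in the ROI")
    return float(a @ b) / denom


def flip180(image: Image2D) -> Image2D:
    """Flip an image vertically and horizontally (180-degree rotation)."""
    return Image2D(image.pixels[::-1, ::-1].copy(), image.pixel_size_nm, image.channel)


def pcc_flipped_control(
    image_a: Image2D, image_b: Image2D, roi: RegionOfInterest
) -> float:
    """Chance-overlap PCC control: correlate channel A with channel B rotated 180 deg.

    The full second channel is rotated before the ROI mask is applied, so the
    mask itself stays in place; this mimics an unrelated distribution with
    identical first-order intensity statistics.
    """
    return pcc(image_a, flip180(image_b), roi)
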