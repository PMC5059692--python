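"""Periphery representation by edge granularity.

Single invading cells scattered in the matrix cannot be segmented (or
counted) reliably from a bright-field cross-section, but they create local
texture: the more cells in an area, the higher its granularity and hence
the number of detected edges.  A Canny edge map over the full frame is
therefore used as a density proxy for the periphery; it may overlap the
core and halo, which is resolved later in the overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_otsu

from .image_io import BinaryMask, Micrograph
from .preprocessing import PreprocessConfig, background_subtract

__all__ = ["CannyConfig", "auto_canny_thresholds", "extract_periphery"]


@dataclass
class CannyConfig:
    """Canny edge-detector parameters on the 0--255 intensity scale.

    When the hysteresis thresholds are left unset, the high threshold is
    the Otsu threshold of the Sobel gradient magnitude of the pre-smoothed
    image and the low threshold is half of it — a reproducible heuristic
    that adapts to image contrast.
    """

    low_threshold: Optional[float] = None
    high_threshold: Optional[float] = None
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")
        if (
            self.low_threshold is not None
            and self.high_threshold is not None
            and not self.low_threshold < self.high_threshold
        ):
            raise ValueError("low_threshold must be below high_threshold")


def auto_canny_thresholds(pixels: np.ndarray, sigma: float) -> tuple[float, float]:
    """(low, high) hysteresis thresholds from the gradient-magnitude histogram."""
    smoothed = ndimage.gaussian_filter(pixels, sigma=sigma, mode="nearest")
    gy = ndimage.sobel(smoothed, axis=0, mode="nearest")
    gx = ndimage.sobel(smoothed, axis=1, mode="nearest")
    magnitude = np.hypot(gy, gx)
    if magnitude.max() == magnitude.min():
        # flat gradient field: any positive threshold yields no edges
        return 1.0, 2.0
    high = float(threshold_otsu(magnitude, nbins=256))
    return high / 2.0, high


def extract_periphery(
    img: Micrograph,
    cfg: CannyConfig | None = None,
    pre: PreprocessConfig | None = None,
) -> BinaryMask:
    """Binary edge map of the full frame (periphery density proxy).

    Illumination correction is applied first only when
    ``pre.apply_background_subtraction_to_periphery`` is set: it helps with
    extreme gradients or severe under-exposure but systematically shrinks
    the periphery on normally exposed images.
    """
    cfg = cfg or CannyConfig()
    pre = pre or PreprocessConfig()
    work = img
    if pre.apply_background_subtraction_to_periphery:
        work = background_subtract(img, pre)

    low, high = cfg.low_threshold, cfg.high_threshold
    if low is None or high is None:
        auto_low, auto_high = auto_canny_thresholds(work.pixels, cfg.smoothing_sigma)
        low = auto_low if low is None else low
        high = auto_high if high is None else high
    edges = canny(
        work.pixels,
        sigma=cfg.smoothing_sigma,
        low_threshold=low,
        high_threshold=high,
    )
    return BinaryMask(edges, "periphery")
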