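"""Reading and writing micrographs and segmentation masks.

All images are canonicalized to a single-channel representation on the
0--255 intensity scale regardless of the source bit depth, because the
density quantification downstream is defined on that scale.  Coordinates
are row-major, origin at the top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import imageio.v3 as iio

__all__ = ["Micrograph", "BinaryMask", "load_micrograph", "save_mask", "load_mask"]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

MIN_SIDE = 64


@dataclass
class Micrograph:
    """A calibrated grayscale micrograph.

    Parameters
    ----------
    pixels:
        2-D float array of intensities in ``[0, 255]``.
    microns_per_pixel:
        Optional spatial calibration (must be positive when given); enables
        reporting of halo surface area in square microns.
    label:
        Free-text sample/day identifier.
    """

    pixels: np.ndarray
    microns_per_pixel: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValueError(
                f"image {h}x{w} below minimum meaningful field {MIN_SIDE}x{MIN_SIDE}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.microns_per_pixel is not None and not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Micrograph":
        """Copy of this micrograph with new pixel data, same calibration."""
        return Micrograph(pixels, self.microns_per_pixel, self.label)


@dataclass
class BinaryMask:
    """A per-region segmentation result aligned with its source micrograph."""

    pixels: np.ndarray
    region_kind: str = "overlay"  # core | halo | periphery | overlay

    _KINDS = frozenset({"core", "halo", "periphery", "overlay"})

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.region_kind not in self._KINDS:
            raise ValueError(f"unknown region kind {self.region_kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()


def _to_gray_255(arr: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel image to one channel by luminance."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"cannot interpret {arr.shape[2]}-channel image")
        arr = arr.astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    return arr.astype(np.float64)


def load_micrograph(
    path: str | Path, microns_per_pixel: Optional[float] = None
) -> Micrograph:
    """Read a TIFF/PNG/JPEG micrograph as a canonical grayscale ``Micrograph``.

    RGB inputs are converted by BT.601 luminance weighting; 16-bit inputs are
    rescaled linearly by their full dtype range onto ``[0, 255]``.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures
        raise IOError(f"cannot decode image file {path}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-sized image in {path}")

    src_dtype = raw.dtype
    gray = _to_gray_255(raw)
    if np.issubdtype(src_dtype, np.integer):
        full_scale = np.iinfo(src_dtype).max
        if full_scale != 255:
            gray = gray * (255.0 / full_scale)
    else:
        # float input assumed already on a 0..1 or 0..255 scale
        if gray.max() <= 1.0:
            gray = gray * 255.0
    gray = np.clip(gray, 0.0, 255.0)
    return Micrograph(gray, microns_per_pixel=microns_per_pixel, label=path.stem)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask losslessly as an 8-bit image (foreground=255)."""
    path = Path(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise IOError(f"mask output must be PNG or TIFF, got {path.suffix!r}")
    out = np.where(mask.pixels, 255, 0).astype(np.uint8)
    try:
        iio.imwrite(path, out)
    except Exception as exc:
        raise IOError(f"cannot write mask to {path}") from exc


def load_mask(path: str | Path, region_kind: str = "overlay") -> BinaryMask:
    """Read back a mask written by :func:`save_mask` (bit-exact round trip)."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return BinaryMask(raw > 127, region_kind)
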