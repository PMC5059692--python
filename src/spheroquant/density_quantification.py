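"""Binarization-density quantification.

The three region masks are combined into a single overlay, and the overlay
is converted into a density map: the frame is split into square tiles
(16x16 px by default), each tile scores the fraction of its pixels that
are foreground, stretched onto 0--255 (all foreground = 255, empty = 0),
the per-tile values are expanded back to full resolution and smoothed with
a Gaussian so adjacent tiles blend.  Integrating the map over the frame
gives a size measure that reflects not just the footprint area but how
densely it is populated — an invasive spheroid with a wide scattered-cell
annulus integrates higher than a purely proliferative one of the same core
size.  Per-sample time series are normalized to day 0, which cancels both
the arbitrary density units and any static structures (debris, resident
cells) present from the start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask

__all__ = [
    "DensityMap",
    "SpheroidMeasurement",
    "AssaySeries",
    "combine_overlay",
    "density_map",
    "integrate",
    "relative_series",
]

DEFAULT_TILE_SIZE = 16


@dataclass
class DensityMap:
    """Tile-averaged, smoothed density on the 0--255 scale, full resolution."""

    values: np.ndarray
    tile_size: int
    smoothing_sigma: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")


@dataclass
class SpheroidMeasurement:
    """Quantification of one image: integrated density plus halo area."""

    integrated_density: float
    halo_area_px: int = 0
    halo_area_um2: Optional[float] = None
    label: str = ""
    day: int = 0


@dataclass
class AssaySeries:
    """Per-sample time series, normalized to its own day 0 (day 0 = 1)."""

    measurements: list[SpheroidMeasurement]
    relative_sizes: list[float]
    label: str = ""


def combine_overlay(
    core: BinaryMask, halo: BinaryMask, periphery: BinaryMask
) -> BinaryMask:
    """Pixel-wise union of the three region masks."""
    if not (core.shape == halo.shape == periphery.shape):
        raise ValueError("region masks must share one shape")
    return BinaryMask(core.pixels | halo.pixels | periphery.pixels, "overlay")


def tile_average(
    overlay: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE
) -> np.ndarray:
    """Per-tile foreground fraction stretched to 0--255, at full resolution.

    Every pixel of a tile carries the tile's value.  Tiles on the right and
    bottom edges may be partial; they are averaged over their actual pixel
    count so the 0--255 range is preserved.
    """
    h, w = overlay.shape
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile_size {tile_size} exceeds image dimensions {h}x{w}")
    fg = overlay.astype(np.float64)
    row_idx = np.arange(0, h, tile_size)
    col_idx = np.arange(0, w, tile_size)
    sums = np.add.reduceat(np.add.reduceat(fg, row_idx, axis=0), col_idx, axis=1)
    ones = np.ones_like(fg)
    counts = np.add.reduceat(np.add.reduceat(ones, row_idx, axis=0), col_idx, axis=1)
    tiles = 255.0 * sums / counts
    expanded = np.repeat(np.repeat(tiles, tile_size, axis=0), tile_size, axis=1)
    return expanded[:h, :w]


def density_map(
    overlay: BinaryMask,
    tile_size: int = DEFAULT_TILE_SIZE,
    smoothing_sigma: Optional[float] = None,
) -> DensityMap:
    """Tile-average the overlay and blend adjacent tiles with a Gaussian.

    ``smoothing_sigma`` defaults to ``tile_size`` pixels; pass 0 to disable
    smoothing (raw tile values).
    """
    if smoothing_sigma is None:
        smoothing_sigma = float(tile_size)
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be non-negative")
    values = tile_average(overlay.pixels, tile_size)
    if smoothing_sigma > 0:
        values = ndimage.gaussian_filter(values, sigma=smoothing_sigma, mode="nearest")
    return DensityMap(np.clip(values, 0.0, 255.0), tile_size, smoothing_sigma)


def integrate(dmap: DensityMap) -> float:
    """Integrated density: plain sum of the map over the whole frame."""
    return float(dmap.values.sum())


def radial_falloff_steepness(dmap: DensityMap, bin_width: int = 4) -> float:
    """Mean |d(density)/d(radius)| over the radial falloff annulus.

    The azimuthally averaged density profile is binned from the image
    center outward; the steepness is the mean absolute radial slope over
    the falloff region, i.e. where the profile lies between 5% and 95% of
    its peak.  A compact, purely proliferative spheroid drops from its
    255-plateau over a narrow annulus (steep); a spheroid shedding a wide
    annulus of scattered cells decays gradually (soft).
    """
    h, w = dmap.values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    bins = np.arange(0, min(h, w) / 2, bin_width)
    profile = np.array(
        [dmap.values[(r >= a) & (r < a + bin_width)].mean() for a in bins]
    )
    peak = profile.max()
    if peak <= 0:
        return 0.0
    falloff = (profile > 0.05 * peak) & (profile < 0.95 * peak)
    if not falloff.any():
        return 0.0
    slope = np.gradient(profile, bin_width)
    return float(np.abs(slope[falloff]).mean())


def relative_series(
    measurements: Sequence[SpheroidMeasurement], label: str = ""
) -> AssaySeries:
    """Normalize a day-ordered series to its day-0 integrated density.

    The day-0 measurement must be present with positive integrated density;
    its relative size is exactly 1.
    """
    ms = sorted(measurements, key=lambda m: m.day)
    if not ms or ms[0].day != 0:
        raise ValueError("series must contain a day-0 measurement")
    base = ms[0].integrated_density
    if base <= 0:
        raise ValueError("degenerate assay: day-0 integrated density is zero")
    rel = [m.integrated_density / base for m in ms]
    rel[0] = 1.0
    return AssaySeries(ms, rel, label=label or ms[0].label)
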