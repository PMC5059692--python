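"""Halo segmentation by iterative seeded flooding with a border stop.

Otsu thresholding under-covers a smoothly spread-out core: the dense ring
of cells escaping the spheroid is brighter than the core but still much
darker than the matrix.  The halo stage recovers it by watershed-style
flooding: starting from the core as seed, the dark region is flooded level
by level outwards over the *original* (non-illumination-corrected) image —
correction would compress exactly the contrast the flood relies on.  The
flood inevitably escapes into the background and reaches the image border;
the flooded area of the last level before any pixel touches the 1-px
border frame is the halo.  For a compact spheroid with a sharp edge this
reproduces the core; for a diffuse one it extends the core over the dense
surrounding region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, Micrograph

__all__ = ["WatershedTrace", "HaloResult", "flood_levels", "extract_halo"]

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 8-connectivity
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class WatershedTrace:
    """Ordered snapshots of the flooded region, one per flooding level.

    ``iterations[0]`` is the seed itself; snapshots are nested
    (``iterations[i] <= iterations[i+1]`` pixel-wise).  ``stop_index`` is the
    first iteration whose flooded set touches the border frame, or ``None``
    if none does.
    """

    iterations: list[np.ndarray] = field(default_factory=list)
    stop_index: Optional[int] = None


@dataclass
class HaloResult:
    mask: BinaryMask
    area_px: int
    area_um2: Optional[float] = None
    #: seed already touched the border; the halo degenerates to the seed
    border_degenerate: bool = False
    trace: Optional[WatershedTrace] = None


def _border_frame(shape: tuple[int, int]) -> np.ndarray:
    frame = np.zeros(shape, dtype=bool)
    frame[0, :] = frame[-1, :] = True
    frame[:, 0] = frame[:, -1] = True
    return frame


def flood_levels(
    pixels: np.ndarray,
    seed: np.ndarray,
    levels: int = 256,
    connectivity: int = 8,
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(level, flooded_mask)`` for successive intensity levels.

    The 0--255 intensity scale is quantized into ``levels`` steps (the
    default 256 floods one gray level at a time).  At each step the flooded
    set is the seed together with every pixel of intensity <= level
    connected to it (dark-object polarity), which makes the sets nested by
    construction.  Levels below the darkest seed pixel cannot grow the
    flood and are skipped.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    lo = float(pixels[seed].min())
    all_levels = np.linspace(0.0, 255.0, num=max(int(levels), 2))
    for level in all_levels[all_levels >= lo - 1e-9]:
        reachable = (pixels <= level) | seed
        labels, _ = ndimage.label(reachable, structure=struct)
        seed_labels = np.unique(labels[seed])
        flooded = np.isin(labels, seed_labels[seed_labels > 0])
        yield float(level), flooded


def extract_halo(
    img: Micrograph,
    core: BinaryMask,
    levels: int = 256,
    connectivity: int = 8,
    keep_trace: bool = False,
) -> HaloResult:
    """Grow the core outward by level flooding; stop at the image border.

    ``img`` must be the unsubtracted original.  Returns the flooded region
    of the last level before the flood touches the 1-pixel border frame,
    which always contains the seed.  If the seed itself touches the border
    the result degenerates to the seed and is flagged.
    """
    if core.is_empty():
        raise ValueError("halo requires a non-empty core seed")
    if core.shape != img.shape:
        raise ValueError("core mask shape does not match image")
    seed = core.pixels
    frame = _border_frame(img.shape)

    def _result(mask: np.ndarray, degenerate: bool, trace: Optional[WatershedTrace]):
        area_px = int(mask.sum())
        area_um2 = None
        if img.microns_per_pixel is not None:
            area_um2 = area_px * img.microns_per_pixel**2
        return HaloResult(
            BinaryMask(mask, "halo"), area_px, area_um2, degenerate, trace
        )

    trace = WatershedTrace(iterations=[seed.copy()]) if keep_trace else None
    if (seed & frame).any():
        if trace is not None:
            trace.stop_index = 0
        return _result(seed.copy(), True, trace)

    previous = seed.copy()
    for _, flooded in flood_levels(img.pixels, seed, levels, connectivity):
        if trace is not None:
            trace.iterations.append(flooded)
        if (flooded & frame).any():
            if trace is not None:
                trace.stop_index = len(trace.iterations) - 1
            return _result(previous, False, trace)
        previous = flooded
    # Flood never reached the border (can only happen if the image maximum
    # region is disconnected from the frame); the last level is the halo.
    return _result(previous, False, trace)
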