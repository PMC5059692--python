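"""Spheroid core segmentation.

The dense central mass of a bright-field spheroid is darker than the
surrounding matrix, so after illumination correction a global Otsu
threshold separates it well.  Thresholding alone also picks up debris and
stray cell aggregates; a set of shape-plausibility checks (minimum area,
centration, solidity) discards implausible objects and the most appropriate
surviving component is kept as the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .image_io import BinaryMask, Micrograph
from .preprocessing import PreprocessConfig, background_subtract

__all__ = ["PlausibilityCriteria", "otsu_threshold", "extract_core"]


@dataclass
class PlausibilityCriteria:
    """Shape checks applied to thresholded components before core selection.

    min_area_fraction
        Minimum component area as a fraction of the image area; rejects dust
        and isolated cells.
    max_center_offset_fraction
        Maximum centroid distance from the image center, as a fraction of
        the half-diagonal; the assay places one spheroid per well, roughly
        centered in the field.
    min_solidity
        Minimum area / convex-hull-area ratio; spheroid cores are
        near-convex blobs, shadows and streaks are not.
    """

    min_area_fraction: float = 0.001
    max_center_offset_fraction: float = 0.5
    min_solidity: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must be in (0, 1)")
        if not 0 < self.max_center_offset_fraction <= 1:
            raise ValueError("max_center_offset_fraction must be in (0, 1]")
        if not 0 < self.min_solidity <= 1:
            raise ValueError("min_solidity must be in (0, 1]")


def otsu_threshold(img: Micrograph) -> float:
    """Otsu threshold of the 256-bin intensity histogram.

    Returns the threshold maximizing the between-class variance; pixels at or
    below it form the dark (cell) class.  A constant image has no separable
    classes and raises ``ValueError``.
    """
    px = img.pixels
    if px.max() == px.min():
        raise ValueError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(px, bins=256, range=(0.0, 256.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(threshold_otsu(hist=(counts, centers)))


def extract_core(
    img: Micrograph,
    criteria: PlausibilityCriteria | None = None,
    cfg: PreprocessConfig | None = None,
) -> BinaryMask:
    """Segment the spheroid core.

    Pipeline: illumination correction, Otsu threshold, keep the dark class,
    label 8-connected components, discard components failing the
    plausibility criteria, keep the largest survivor (ties broken by
    centration) and fill its interior holes.  An empty mask is a legal
    outcome — an image with no spheroid yields no core.
    """
    criteria = criteria or PlausibilityCriteria()
    corrected = background_subtract(img, cfg)
    try:
        thr = otsu_threshold(corrected)
    except ValueError:
        return BinaryMask(np.zeros(img.shape, dtype=bool), "core")
    dark = corrected.pixels <= thr

    labels = label(dark, connectivity=2)
    h, w = img.shape
    img_area = h * w
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    half_diag = np.hypot(h / 2.0, w / 2.0)

    best = None  # (area, -center_distance, label_id)
    for region in regionprops(labels):
        if region.area < criteria.min_area_fraction * img_area:
            continue
        offset = np.linalg.norm(np.asarray(region.centroid) - center)
        if offset > criteria.max_center_offset_fraction * half_diag:
            continue
        if region.solidity < criteria.min_solidity:
            continue
        key = (region.area, -offset)
        if best is None or key > best[0]:
            best = (key, region.label)

    if best is None:
        return BinaryMask(np.zeros(img.shape, dtype=bool), "core")
    chosen = labels == best[1]
    # The halo stage seeds a watershed from this mask, so it must be solid.
    return BinaryMask(ndimage.binary_fill_holes(chosen), "core")
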