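"""End-to-end analysis of a single micrograph and of day-ordered series.

Order of operations per image: optional gamma correction of the raw image;
core segmentation (which applies illumination correction internally); halo
flooding seeded by the core on the original, uncorrected image; Canny
periphery over the full frame; union overlay; tile density map; integrated
density.  Every step is deterministic, so the full pipeline is bit-exact
reproducible for a fixed image and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

from .core_extraction import PlausibilityCriteria, extract_core
from .density_quantification import (
    DensityMap,
    SpheroidMeasurement,
    combine_overlay,
    density_map,
    integrate,
)
from .halo_extraction import HaloResult, extract_halo
from .image_io import BinaryMask, Micrograph
from .periphery_extraction import CannyConfig, extract_periphery
from .preprocessing import PreprocessConfig, apply_gamma

__all__ = ["AnalysisConfig", "ImageAnalysis", "analyze_image"]


@dataclass
class AnalysisConfig:
    """All tunables of the analysis pipeline, with field defaults."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    core: PlausibilityCriteria = field(default_factory=PlausibilityCriteria)
    periphery: CannyConfig = field(default_factory=CannyConfig)
    halo_levels: int = 256
    halo_connectivity: int = 8
    tile_size: int = 16
    smoothing_sigma: Optional[float] = None  # None -> tile_size

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for run manifests."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        """Build from a nested mapping (parsed YAML)."""
        cfg = cls()
        pre = data.get("preprocess", {})
        cfg.preprocess = PreprocessConfig(
            blur_sigma_fraction=pre.get("blur_sigma_fraction", 0.125),
            gamma=pre.get("gamma", 1.0),
            apply_background_subtraction_to_periphery=pre.get(
                "periphery_background_subtraction", False
            ),
        )
        core = data.get("core", {})
        cfg.core = PlausibilityCriteria(
            min_area_fraction=core.get("min_area_fraction", 0.001),
            max_center_offset_fraction=core.get("max_center_offset", 0.5),
            min_solidity=core.get("min_solidity", 0.7),
        )
        per = data.get("periphery", {})
        cfg.periphery = CannyConfig(
            low_threshold=per.get("low"),
            high_threshold=per.get("high"),
            smoothing_sigma=per.get("sigma", 1.0),
        )
        halo = data.get("halo", {})
        cfg.halo_levels = halo.get("levels", 256)
        cfg.halo_connectivity = halo.get("connectivity", 8)
        dens = data.get("density", {})
        cfg.tile_size = dens.get("tile_size", 16)
        cfg.smoothing_sigma = dens.get("smoothing_sigma")
        return cfg


@dataclass
class ImageAnalysis:
    """All artifacts of one image's analysis."""

    core: BinaryMask
    halo: Optional[HaloResult]
    periphery: BinaryMask
    overlay: BinaryMask
    dmap: DensityMap
    measurement: SpheroidMeasurement


def analyze_image(
    img: Micrograph, config: AnalysisConfig | None = None, day: int = 0
) -> ImageAnalysis:
    """Run the full three-region segmentation and density quantification."""
    config = config or AnalysisConfig()

    if config.preprocess.gamma != 1.0:
        img = apply_gamma(img, config.preprocess.gamma)

    core = extract_core(img, config.core, config.preprocess)
    halo: Optional[HaloResult] = None
    if not core.is_empty():
        halo = extract_halo(
            img, core, levels=config.halo_levels, connectivity=config.halo_connectivity
        )
        halo_mask = halo.mask
    else:
        halo_mask = BinaryMask(core.pixels.copy(), "halo")
    periphery = extract_periphery(img, config.periphery, config.preprocess)

    overlay = combine_overlay(core, halo_mask, periphery)
    dmap = density_map(overlay, config.tile_size, config.smoothing_sigma)
    measurement = SpheroidMeasurement(
        integrated_density=integrate(dmap),
        halo_area_px=halo.area_px if halo else 0,
        halo_area_um2=halo.area_um2 if halo else None,
        label=img.label,
        day=day,
    )
    return ImageAnalysis(core, halo, periphery, overlay, dmap, measurement)
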