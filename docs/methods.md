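# Methods

## Problem setting and model

A bright-field micrograph of a collagen-embedded tumor spheroid is a 2-D
cross-section of a 3-D object: the core is too dense for any cell to be
resolved, single invading cells hide cells in front of and behind the focal
plane, and the outermost cells may leave the camera aperture. The package
therefore treats the image photographically, not biologically: it segments
three regions defined purely by their appearance and converts the combined
segmentation into a *binarization density* — the local fraction of
segmented pixels — which acts as a proxy for cell density without any cell
counting. All quantities derived from it are relative (each sample
normalized to its own day 0), so the proxy's arbitrary units cancel.

### Region segmentation

**Core.** The image is first illumination-corrected: a strong Gaussian blur
(sigma = min(H, W)/8 by default) estimates the illumination field; each
pixel is shifted by the difference between the blurred image at that pixel
and the global mean intensity, and clipped to [0, 255]. On a constant image
the correction is a no-op; on a pure linear gradient it flattens the field
away from the borders while structures much smaller than the blur kernel
survive. Otsu's threshold (256-bin histogram) then splits the corrected
image; the below-threshold (dark) class is the candidate cell material,
since bright-field spheroids are darker than the matrix. Connected
components (8-connectivity) are filtered by plausibility — area ≥ 0.1% of
the frame, centroid within half the half-diagonal of the image center,
solidity ≥ 0.7 — and the largest survivor (ties broken by centration)
becomes the core after interior hole filling, so it can seed the watershed.
An empty core is a legal outcome: an image without a spheroid yields no
spheroid. The plausibility thresholds are this package's own
concretization of "shape-based checks"; they are exposed in configuration.

**Halo.** Otsu under-segments a smoothly spread-out core, so the core is
grown outward on the *original* image (correction would compress exactly
the contrast the growth relies on): the 0–255 gray scale is quantized into
256 levels, and at each level the flooded set is the seed plus every pixel
of intensity ≤ level 8-connected to it. The flooded sets are nested by
construction. Once any flooded pixel lies in the 1-px border frame the
flooding stops, and the previous level's flooded set is the halo — the
flood always escapes into the background eventually, and the last
pre-escape set covers the dense region without the background. For a
sharp-edged spheroid the halo nearly equals the core; for a diffuse one it
extends over the dense rim. The flood prefers darker regions, which
slightly biases the halo shape, but the subsequent tile averaging absorbs
this. With a pixels-per-micron calibration the halo area is also reported
in µm².

**Periphery.** A Canny edge map over the whole frame. Its purpose is not
cell detection: edge-pixel count in a window grows with the number of cells
there (granularity), so the edge map contributes a density gradient where
scattered cells sit. Hysteresis thresholds default to the Otsu threshold of
the Sobel gradient magnitude of the pre-smoothed image (high) and half of
it (low); smoothing sigma defaults to 1 px. On normally exposed images the
periphery is computed without illumination correction — the correction
systematically thins edges — but a flag enables it for severely
under-exposed images or extreme gradients, where false edges otherwise
dominate.

### Density map and size measure

The three masks are united (pixel-wise OR); overlaps are harmless since a
pixel is simply foreground. The frame is split into 16×16-px tiles (tiles
at the right/bottom edge may be partial and are averaged over their actual
pixel count); each tile scores 255 × foreground fraction; values are
expanded back to pixel resolution and smoothed with a Gaussian of sigma =
tile size, blending adjacent tiles. The map is clipped to [0, 255]; the
core always sits at the 255 ceiling. Integrated density is the plain sum
of the smoothed map, and relative size divides by the day-0 integral
(day 0 ≡ 1 exactly, enforced rather than recomputed, to avoid float
residue). Tile size was read as a pixel dimension, not a grid subdivision,
so map resolution is independent of image size; both it and the smoothing
sigma are configurable.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| blur_sigma_fraction | 0.125 | of min(H,W) | blur spans the core: removes field-scale gradients, keeps cells |
| gamma | 1.0 | – | raise for high-brightness/low-contrast images |
| core.min_area_fraction | 0.001 | of frame | rejects dust and single cells |
| core.max_center_offset | 0.5 | of half-diagonal | one roughly centered spheroid per well |
| core.min_solidity | 0.7 | – | cores are near-convex blobs |
| halo.levels | 256 | levels/255 gray | one flood step per gray level |
| halo.connectivity | 8 | – | avoids treating diagonal contacts as gaps |
| periphery.sigma | 1.0 | px | standard pre-Canny smoothing |
| tile_size | 16 | px | tile scale of the density map |
| smoothing_sigma | tile_size | px | "adjacent tiles averaged" reading |

## Synthetic scenes

The generator renders what the assay's imaging step produces: a dark disk
core (intensity 60 on background 200 by default), a linear radial intensity
ramp standing in for the dense rim, Gaussian-profiled dark blobs for single
cells placed uniformly in an annulus, one of five illumination models
(flat; linear gradient; Gaussian corner shadow; global under-exposure;
high-brightness/low-contrast gain), additive Gaussian camera noise
(sigma = 2 gray levels by default) and 8-bit quantization. Ground truth
(core mask, dense-region mask, cell centers) is exact by construction, and
a single seeded RNG stream makes every render reproducible. Time series
reuse one noise field across days so that day-to-day differences reflect
geometry growth only.

What the generator does **not** emulate: collagen fiber texture, optical
point-spread blur, defocus, cell debris and matrix impurities, and
non-radial invasion patterns (ring-like profiles). Passing tests on these
scenes therefore demonstrate the algorithmic contracts — segmentation
accuracy against known geometry, monotonicity, illumination robustness,
determinism — not performance on any particular real cell line.

The illumination-robustness experiment uses a 1024×1024-px scene at
1 µm/px with a 200-px core and 20-px rim, giving a halo surface area near
1.5·10⁵ µm² — the size of a typical compact glioma spheroid early in an
assay. Scale matters here: the flooding stop level sits just below the
background intensity, and the set of near-threshold noisy background
pixels picked up at that level scales with the halo *perimeter*, while the
halo area scales with radius squared. On miniature scenes this fringe is
several percent of the area and dominates the variance between
illumination conditions; at realistic halo sizes it drops below 1%. The
global conditions (under-exposure offset, contrast gain) are monotone
intensity maps and leave the per-gray-level flooding order unchanged by
construction; the corner shadow is the genuinely spatial perturbation, and
its effect is limited to the shadow's differential darkening across the
spheroid rim.

## Numerical choices and degenerate inputs

- Intensities are canonicalized to float64 on the 0–255 scale at load time
  (16-bit inputs divided by their dtype range, RGB collapsed with BT.601
  weights); masks round-trip bit-exactly through 8-bit PNG/TIFF.
- A constant image has no Otsu threshold; core extraction returns an empty
  mask rather than propagating the error.
- An empty core is a validation error for halo extraction (nothing to
  seed); a core already touching the border degenerates to halo = core and
  is flagged.
- Component selection tie-break: largest area, then smallest
  centroid-to-center distance.
- Flood levels below the darkest seed pixel cannot grow the flood and are
  skipped.
- Gaussian filters use replicate ("nearest") boundary handling, so a
  constant field is exactly invariant under smoothing.
- Day-0 relative size is set to 1.0 exactly; a zero day-0 integral or a
  missing day-0 image aborts the sample with a validation error.

## Problem sizes

Tests run scenes of 256–512 px; the acceptance script uses a 384-px scene
for the density ceiling and four 1024-px renders for the illumination
experiment (about ten seconds end to end). These sizes were chosen as the
smallest at which the measured quantities are scale-stable (see the fringe
discussion above).

## Known limitations

- The plausibility criteria and Canny thresholds are reconstructions of
  behavior that the original analysis described only qualitatively; they
  are configuration, not ground truth.
- The flood's darker-region bias means the halo is not a level set of
  distance from the core; only density-map-level quantities should be
  compared across very different illumination setups.
- Group statistics across samples/conditions (ANOVA etc.) are out of
  scope; the package stops at per-sample relative-size series.
- One spheroid per image is assumed; multi-spheroid wells are not
  supported.
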