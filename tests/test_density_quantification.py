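import numpy as np
import pytest

from spheroquant import (
    BinaryMask,
    Micrograph,
    SpheroidMeasurement,
    analyze_image,
    combine_overlay,
    density_map,
    integrate,
    radial_falloff_steepness,
    relative_series,
    render_scene,
)
from spheroquant.density_quantification import tile_average
from spheroquant.synthetic_fixtures import SpheroidScene


def _mask(px, kind="overlay"):
    return BinaryMask(px, kind)


class TestCombineOverlay:
    def test_union_identity_with_empty_periphery(self):
        core = _mask(np.eye(32, dtype=bool), "core")
        halo = _mask(np.eye(32, dtype=bool), "halo")
        peri = _mask(np.zeros((32, 32), dtype=bool), "periphery")
        overlay = combine_overlay(core, halo, peri)
        assert np.array_equal(overlay.pixels, core.pixels)

    def test_disjoint_areas_add(self):
        a = np.zeros((32, 32), dtype=bool)
        b = np.zeros((32, 32), dtype=bool)
        a[:8], b[20:] = True, True
        overlay = combine_overlay(_mask(a, "core"), _mask(a, "halo"), _mask(b, "periphery"))
        assert overlay.area_px == a.sum() + b.sum()

    def test_overlay_superset_of_inputs(self):
        rng = np.random.default_rng(0)
        masks = [rng.random((32, 32)) > 0.7 for _ in range(3)]
        overlay = combine_overlay(
            _mask(masks[0], "core"), _mask(masks[1], "halo"), _mask(masks[2], "periphery")
        )
        for m in masks:
            assert np.all(m <= overlay.pixels)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_overlay(
                _mask(np.zeros((32, 32), bool), "core"),
                _mask(np.zeros((16, 16), bool), "halo"),
                _mask(np.zeros((32, 32), bool), "periphery"),
            )


class TestDensityMap:
    def test_full_foreground_is_255_everywhere(self):
        overlay = _mask(np.ones((64, 64), dtype=bool))
        dm = density_map(overlay)
        assert np.allclose(dm.values, 255.0)

    def test_empty_overlay_is_zero(self):
        dm = density_map(_mask(np.zeros((64, 64), dtype=bool)))
        assert np.all(dm.values == 0.0)

    def test_half_foreground_tile_scores_127_5(self):
        px = np.zeros((64, 64), dtype=bool)
        px[16:32, 16:24] = True  # half of the tile at (1,1)
        dm = density_map(_mask(px), tile_size=16, smoothing_sigma=0)
        assert np.allclose(dm.values[16:32, 16:32], 127.5)
        assert np.all(dm.values[:16] == 0.0)

    def test_tile_values_match_pixel_count_oracle(self):
        rng = np.random.default_rng(1)
        px = rng.random((80, 80)) > 0.5
        vals = tile_average(px, 16)
        for ty in range(5):
            for tx in range(5):
                tile = px[ty * 16 : (ty + 1) * 16, tx * 16 : (tx + 1) * 16]
                expected = 255.0 * tile.sum() / tile.size
                assert vals[ty * 16, tx * 16] == pytest.approx(expected)

    def test_partial_edge_tiles_averaged_over_actual_pixels(self):
        px = np.ones((70, 70), dtype=bool)
        vals = tile_average(px, 16)
        assert np.allclose(vals, 255.0)  # full coverage stays full on edges

    def test_tile_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            density_map(_mask(np.zeros((32, 32), bool)), tile_size=64)

    def test_values_bounded(self):
        rng = np.random.default_rng(2)
        dm = density_map(_mask(rng.random((100, 100)) > 0.3))
        assert dm.values.min() >= 0.0 and dm.values.max() <= 255.0


class TestIntegrate:
    def test_extremes(self):
        assert integrate(density_map(_mask(np.zeros((64, 64), bool)))) == 0.0
        full = density_map(_mask(np.ones((64, 64), bool)))
        assert integrate(full) == pytest.approx(255.0 * 64 * 64)

    def test_tile_aligned_mass_conservation(self):
        """Without smoothing, the integral is 255 x foreground count."""
        rng = np.random.default_rng(3)
        # foreground made of whole 16 px tiles
        tiles = rng.random((4, 4)) > 0.5
        px = np.repeat(np.repeat(tiles, 16, axis=0), 16, axis=1)
        dm = density_map(_mask(px), tile_size=16, smoothing_sigma=0)
        assert integrate(dm) == pytest.approx(255.0 * px.sum())


class TestRelativeSeries:
    def _m(self, day, integ):
        return SpheroidMeasurement(integrated_density=integ, day=day)

    def test_day0_is_exactly_one(self):
        series = relative_series([self._m(0, 123456.7)])
        assert series.relative_sizes[0] == 1.0

    def test_doubling_gives_two(self):
        series = relative_series([self._m(0, 1000.0), self._m(4, 2000.0)])
        assert series.relative_sizes == [1.0, 2.0]

    def test_growth_series_monotone(self):
        from spheroquant import GrowthModel, render_series

        scene = SpheroidScene(seed=10, core_radius=40.0, n_peripheral_cells=20)
        growth = GrowthModel(4.0, 25, 6.0)
        rendered = render_series(scene, 4, growth)
        ms = [
            SpheroidMeasurement(
                analyze_image(img, day=d).measurement.integrated_density, day=d
            )
            for d, (img, _) in enumerate(rendered)
        ]
        series = relative_series(ms)
        assert all(b > a for a, b in zip(series.relative_sizes, series.relative_sizes[1:]))

    def test_static_debris_cancels_toward_clean_ratio(self):
        """A constant background contribution pushes the ratio toward 1:1 scaling."""
        clean0, clean1 = 1000.0, 3000.0
        debris = 500.0
        contaminated = relative_series(
            [self._m(0, clean0 + debris), self._m(1, clean1 + debris)]
        )
        # ratio with shared debris lies between 1 and the clean ratio
        assert 1.0 < contaminated.relative_sizes[1] < clean1 / clean0

    def test_missing_day0_rejected(self):
        with pytest.raises(ValueError):
            relative_series([self._m(1, 10.0)])

    def test_zero_day0_rejected(self):
        with pytest.raises(ValueError):
            relative_series([self._m(0, 0.0)])


class TestInvasionContrasts:
    def test_proliferative_falloff_steeper_than_invasive(self):
        prol = SpheroidScene(seed=3, core_radius=50.0, halo_width=2.0, n_peripheral_cells=0)
        inv = SpheroidScene(
            seed=3,
            core_radius=50.0,
            halo_width=2.0,
            n_peripheral_cells=150,
            placement_ring=(55.0, 120.0),
        )
        s_prol = radial_falloff_steepness(analyze_image(render_scene(prol)[0]).dmap)
        s_inv = radial_falloff_steepness(analyze_image(render_scene(inv)[0]).dmap)
        assert s_prol > s_inv

    def test_scattered_cell_annulus_increases_integral(self):
        base = SpheroidScene(seed=4, core_radius=50.0, halo_width=2.0, n_peripheral_cells=0)
        plus = SpheroidScene(seed=4, core_radius=50.0, halo_width=2.0, n_peripheral_cells=60)
        i0 = analyze_image(render_scene(base)[0]).measurement.integrated_density
        i1 = analyze_image(render_scene(plus)[0]).measurement.integrated_density
        assert i1 > i0

    def test_translation_changes_integral_by_at_most_3pct(self):
        scene = SpheroidScene(
            seed=6, image_size=(320, 320), core_radius=50.0,
            halo_width=10.0, n_peripheral_cells=30,
        )
        img, _ = render_scene(scene)
        centered = analyze_image(img).measurement.integrated_density
        shifted_px = np.roll(img.pixels, 30, axis=1)  # <10% of width
        shifted = analyze_image(Micrograph(shifted_px)).measurement.integrated_density
        assert abs(shifted - centered) <= 0.03 * centered

    def test_border_cells_still_raise_edge_tile_density(self):
        """Cells partially beyond the frame still contribute edge density."""
        base = SpheroidScene(seed=12, image_size=(256, 256), n_peripheral_cells=0)
        img, _ = render_scene(base)
        px = img.pixels.copy()
        yy, xx = np.mgrid[0:256, 0:256]
        for cy, cx in [(3.0, 80.0), (253.0, 170.0), (128.0, 2.0)]:
            px -= 110.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
        with_cells = analyze_image(Micrograph(np.clip(px, 0, 255)))
        without = analyze_image(img)
        border_band = np.zeros((256, 256), dtype=bool)
        border_band[:16] = border_band[-16:] = True
        border_band[:, :16] = border_band[:, -16:] = True
        assert (
            with_cells.dmap.values[border_band].sum()
            > without.dmap.values[border_band].sum()
        )


class TestEndToEndDeterminism:
    def test_full_pipeline_bit_identical_across_runs(self, compact_render):
        img, _ = compact_render
        r1, r2 = analyze_image(img), analyze_image(img)
        assert np.array_equal(r1.dmap.values, r2.dmap.values)
        assert r1.measurement.integrated_density == r2.measurement.integrated_density
        assert np.array_equal(r1.overlay.pixels, r2.overlay.pixels)
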