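"""Colour-rule segmentation, mask cleanup, hull and trait extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peavigour import (
    EmptyMaskError,
    PlantMask,
    SceneSpec,
    convex_hull_area,
    denoise_mask,
    extract_traits,
    make_scene,
    plant_height,
    segment_plant,
)
from peavigour.synthetic import parametric_plant_shapes

from oracles import brute_hull_fill, flood_fill_components

PLANT = {(r, c) for r in range(20, 70) for c in range(30, 40)}  # 500 px


def block_mask(shape, *blocks):
    m = np.zeros(shape, dtype=bool)
    for r0, r1, c0, c1 in blocks:
        m[r0:r1, c0:c1] = True
    return m


class TestSegmentPlant:
    def test_noiseless_scene_recovered_exactly(self):
        imgs, gt = make_scene(SceneSpec(100, 100, PLANT))
        assert segment_plant(imgs.top, view="top").count == gt.plant_pixels["top"] == 500

    def test_cage_occlusion_reduces_count(self):
        cage = {(r, 35) for r in range(60, 100)}  # occludes 10 plant px
        imgs, gt = make_scene(SceneSpec(100, 100, PLANT, cage))
        assert segment_plant(imgs.top).count == gt.plant_pixels["top"] == 490

    @pytest.mark.parametrize("view", ["top", "side0"])
    def test_noisy_scenes_within_two_percent_of_truth(self, view):
        for seed in range(20):
            spec = SceneSpec(100, 100, PLANT, noise_sd=5.0, seed=seed)
            imgs, gt = make_scene(spec)
            n = segment_plant(imgs.views()[view]).count
            assert abs(n - gt.plant_pixels[view]) <= 0.02 * gt.plant_pixels[view]

    def test_background_colour_change_is_invisible(self):
        a, _ = make_scene(SceneSpec(100, 100, PLANT))
        b, _ = make_scene(SceneSpec(100, 100, PLANT, background_colour=(250, 240, 230)))
        assert segment_plant(a.top).count == segment_plant(b.top).count

    def test_empty_result_is_legal(self):
        img = np.full((20, 20, 3), 245, dtype=np.uint8)
        assert segment_plant(img).count == 0


class TestDenoise:
    def test_large_single_component_unchanged(self):
        m = PlantMask("top", block_mask((50, 50), (10, 35, 10, 30)))
        assert denoise_mask(m, 50).count == m.count == 500

    def test_speckles_below_threshold_removed(self):
        base = block_mask((80, 80), (10, 35, 10, 30))
        rng = np.random.default_rng(0)
        speckled = base.copy()
        placed = 0
        while placed < 12:
            r, c = rng.integers(45, 78, size=2)
            if not speckled[r - 2 : r + 3, c - 2 : c + 3].any():
                speckled[r, c] = True
                placed += 1
        assert denoise_mask(PlantMask("top", speckled), 50).count == 500

    def test_size_threshold_is_strict_less_than(self):
        # components of sizes 49, 50, 51; min_size=50 keeps 50 and 51
        m = block_mask((40, 120), (5, 12, 5, 12), (5, 15, 30, 35), (5, 22, 60, 63))
        sizes = flood_fill_components(m)
        assert sizes == [49, 50, 51]
        cleaned = denoise_mask(PlantMask("top", m), 50)
        assert cleaned.count == 101
        assert flood_fill_components(cleaned.mask) == [50, 51]


class TestConvexHull:
    def test_solid_block(self):
        m = PlantMask("top", block_mask((20, 20), (5, 15, 5, 15)))
        assert convex_hull_area(m) == pytest.approx(0.100)

    def test_four_corners_fill_the_square(self):
        m = np.zeros((20, 20), dtype=bool)
        for r, c in [(5, 5), (5, 14), (14, 5), (14, 14)]:
            m[r, c] = True
        assert convex_hull_area(PlantMask("top", m)) == pytest.approx(0.100)

    def test_single_pixel(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert convex_hull_area(PlantMask("top", m)) == pytest.approx(0.001)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            convex_hull_area(PlantMask("top", np.zeros((5, 5), dtype=bool)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_bruteforce_half_plane_oracle(self, seed):
        """Hull rasterisation matches an exhaustive supporting-half-plane
        search on random masks of <= 200 pixels."""
        rng = np.random.default_rng(seed)
        m = rng.random((12, 12)) < 0.5
        m.flat[rng.integers(0, m.size)] = True  # never empty
        assert m.sum() <= 200
        from peavigour.segmentation import _hull_fill

        assert np.array_equal(_hull_fill(m), brute_hull_fill(m))

    @given(st.integers(0, 10_000))
    def test_hull_is_superset_of_mask(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((10, 10)) < 0.3
        m[5, 5] = True
        from peavigour.segmentation import _hull_fill

        fill = _hull_fill(m)
        assert np.all(fill[m])  # implies TVCOM <= 1


class TestPlantHeight:
    def test_row_span_inclusive(self):
        assert plant_height(PlantMask("side0", block_mask((60, 20), (10, 51, 4, 6)))) == 41

    def test_single_pixel_height_one(self):
        m = np.zeros((9, 9), dtype=bool)
        m[3, 3] = True
        assert plant_height(PlantMask("side0", m)) == 1

    def test_disjoint_blobs_span(self):
        m = block_mask((100, 10), (5, 10, 2, 4), (90, 100, 2, 4))
        assert plant_height(PlantMask("side0", m)) == 95

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            plant_height(PlantMask("side0", np.zeros((5, 5), dtype=bool)))


class TestExtractTraits:
    def test_view_sum_arithmetic(self):
        shapes = parametric_plant_shapes(
            100, 100, {"top": 500, "side0": 400, "side120": 420, "side240": 380}, seed=1
        )
        imgs, _ = make_scene(SceneSpec(100, 100, shapes))
        rec = extract_traits(imgs, min_size=1)
        assert rec.eb_kpix == pytest.approx(1.700)
        assert rec.tva_kpix == pytest.approx(0.500)
        assert not rec.flags

    def test_solid_convex_blob_has_unit_compactness(self):
        solid = {(r, c) for r in range(30, 50) for c in range(30, 55)}
        imgs, _ = make_scene(SceneSpec(100, 100, solid))
        rec = extract_traits(imgs, min_size=1)
        assert rec.tvcom == pytest.approx(1.0)

    def test_plus_sign_compactness_five_ninths(self):
        """A plus of 5 unit squares rasterises to the full 3x3 hull, so
        compactness is 5/9 (cross-checked by the brute-force oracle)."""
        plus = {(40, 41), (41, 40), (41, 41), (41, 42), (42, 41)}
        imgs, _ = make_scene(SceneSpec(100, 100, plus))
        rec = extract_traits(imgs, min_size=1)
        assert rec.tvcom == pytest.approx(5 / 9)
        m = np.zeros((100, 100), dtype=bool)
        for r, c in plus:
            m[r, c] = True
        assert brute_hull_fill(m).sum() == 9

    def test_noiseless_traits_equal_ground_truth(self):
        shapes = parametric_plant_shapes(120, 120, 600, seed=4)
        imgs, gt = make_scene(SceneSpec(120, 120, shapes))
        rec = extract_traits(imgs, min_size=1)
        assert rec.eb_kpix == pytest.approx(sum(gt.plant_pixels.values()) / 1000)
        assert rec.tva_kpix == pytest.approx(gt.plant_pixels["top"] / 1000)
        assert rec.tvch_kpix == pytest.approx(gt.top_hull_pixels / 1000)
        assert rec.eh_pix == max(gt.side_heights.values())
        assert rec.tvcom <= 1.0

    def test_empty_view_flags_instead_of_zeroing(self):
        shapes = parametric_plant_shapes(100, 100, 300, seed=2)
        shapes["top"] = {(r, c) for r in range(40, 60) for c in range(40, 55)}  # 300 px
        shapes["side120"] = {(50, 50)}  # wiped by the size filter
        imgs, _ = make_scene(SceneSpec(100, 100, shapes))
        rec = extract_traits(imgs, min_size=50)
        assert "empty_mask:side120" in rec.flags
        assert np.isnan(rec.eb_kpix)
        assert rec.tva_kpix == pytest.approx(0.300)  # top view unaffected
        assert not np.isnan(rec.eh_pix)  # two side views remain
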