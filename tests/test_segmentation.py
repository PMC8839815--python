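import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.filters import threshold_otsu as skimage_otsu

from conftest import brute_force_otsu, flood_fill_components
from swimarea.segmentation import (
    LabThreshold,
    ROISpec,
    SegmentationWarning,
    binarise,
    count_area,
    crop_roi,
    fill_holes,
    filter_blobs,
    otsu_threshold,
    process_frame,
    replace_pixels,
    threshold_mask,
    water_mask,
    waterline_filter,
)
from swimarea.synthetic_scene import SceneSpec, render_scene

FRONTAL_BOX = LabThreshold(
    l_range=(25.466, 98.620), a_range=(-46.336, 8.860), b_range=(-31.446, 60.616)
)


def lab_pixel(l, a, b):
    return np.array([[[l, a, b]]], dtype=float)


class TestCropRoi:
    def test_full_frame_roi_is_identity(self):
        frame = np.random.default_rng(0).integers(0, 256, (10, 12, 3)).astype(np.uint8)
        out = crop_roi(frame, ROISpec(0, 0, 10, 12))
        assert np.array_equal(out, frame)

    def test_coordinates_are_zero_based_half_open(self):
        frame = (np.arange(10 * 10 * 3) % 256).astype(np.uint8).reshape(10, 10, 3)
        out = crop_roi(frame, ROISpec(top=2, left=3, height=4, width=5))
        assert out.shape == (4, 5, 3)
        assert np.array_equal(out[0, 0], frame[2, 3])

    def test_roi_exceeding_frame_names_the_edge(self):
        frame = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="right edge"):
            crop_roi(frame, ROISpec(0, 6, 4, 5))
        with pytest.raises(ValueError, match="bottom edge"):
            crop_roi(frame, ROISpec(8, 0, 5, 4))


class TestThresholdMask:
    def test_pixel_inside_all_intervals_matches(self):
        assert threshold_mask(lab_pixel(50, 0, 0), FRONTAL_BOX)[0, 0]

    def test_lightness_above_upper_bound_is_excluded(self):
        assert not threshold_mask(lab_pixel(99.0, 0, 0), FRONTAL_BOX)[0, 0]

    def test_boundary_values_are_excluded_strictly(self):
        assert not threshold_mask(lab_pixel(98.620, 0, 0), FRONTAL_BOX)[0, 0]
        assert not threshold_mask(lab_pixel(50, 8.860, 0), FRONTAL_BOX)[0, 0]

    def test_vacuous_intervals_accept_everything(self):
        wide = LabThreshold((-1e9, 1e9), (-1e9, 1e9), (-1e9, 1e9))
        lab = np.random.default_rng(1).normal(50, 30, (5, 5, 3))
        assert threshold_mask(lab, wide).all()

    def test_interval_with_min_not_below_max_rejected(self):
        with pytest.raises(ValueError):
            LabThreshold((5, 5), (0, 1), (0, 1))


class TestReplacePixels:
    def test_empty_mask_is_identity(self):
        frame = np.random.default_rng(2).integers(0, 256, (6, 6, 3)).astype(np.uint8)
        out = replace_pixels(frame, np.zeros((6, 6), bool), (27, 131, 135))
        assert np.array_equal(out, frame)

    def test_full_mask_paints_uniform_colour(self):
        frame = np.random.default_rng(3).integers(0, 256, (4, 5, 3)).astype(np.uint8)
        out = replace_pixels(frame, np.ones((4, 5), bool), (27, 131, 135))
        assert np.array_equal(out, np.full((4, 5, 3), (27, 131, 135), np.uint8))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(mask=hnp.arrays(bool, (8, 9)))
    def test_changes_exactly_the_masked_pixels(self, mask):
        frame = np.full((8, 9, 3), 200, dtype=np.uint8)
        out = replace_pixels(frame, mask, (0, 0, 0))
        changed = np.any(out != frame, axis=-1)
        assert np.array_equal(changed, mask)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            replace_pixels(np.zeros((4, 4, 3), np.uint8), np.zeros((3, 4), bool), (0, 0, 0))


class TestWaterMask:
    @pytest.mark.parametrize("lstar, keep", [(82.5, True), (200.0, False), (5.0, False)])
    def test_keep_interval_is_strict(self, lstar, keep):
        assert water_mask(np.array([[lstar]]), (5.0, 160.0))[0, 0] == keep

    def test_unbounded_range_keeps_all(self):
        vals = np.random.default_rng(4).uniform(0, 255, (6, 6))
        assert water_mask(vals, (-1.0, 256.0)).all()


class TestWaterlineFilter:
    def test_row_zero_keeps_everything(self):
        mask = np.ones((10, 4), bool)
        assert np.array_equal(waterline_filter(mask, 0), mask)

    def test_rows_above_the_line_are_zeroed(self):
        mask = np.ones((100, 3), bool)
        out = waterline_filter(mask, 97)
        assert not out[:97].any()
        assert out[97:].all()
        assert count_area(out) == 3 * 3

    def test_empty_mask_stays_empty(self):
        mask = np.zeros((10, 4), bool)
        assert not waterline_filter(mask, 5).any()

    def test_idempotent(self):
        mask = np.random.default_rng(5).random((20, 8)) > 0.5
        once = waterline_filter(mask, 7)
        assert np.array_equal(waterline_filter(once, 7), once)

    def test_out_of_range_row_rejected(self):
        with pytest.raises(ValueError):
            waterline_filter(np.ones((10, 4), bool), 11)


class TestBinarise:
    def test_bimodal_image_splits_between_the_modes(self):
        gray = np.full((10, 10), 10, np.uint8)
        gray[:, 5:] = 200
        out = binarise(gray)
        assert np.array_equal(out, gray == 200)
        assert 10 <= otsu_threshold(gray) < 200

    def test_constant_image_yields_empty_mask_with_warning(self):
        with pytest.warns(SegmentationWarning):
            out = binarise(np.full((8, 8), 42, np.uint8))
        assert not out.any()

    def test_threshold_matches_exhaustive_search_on_random_rasters(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            gray = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            assert otsu_threshold(gray) == brute_force_otsu(gray)

    def test_threshold_agrees_with_reference_library(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            gray = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            assert otsu_threshold(gray) == int(skimage_otsu(gray))


class TestFilterBlobs:
    def test_zero_min_area_is_identity(self):
        mask = np.random.default_rng(6).random((20, 20)) > 0.7
        assert np.array_equal(filter_blobs(mask, 0), mask)

    def test_small_component_removed_large_retained(self):
        mask = np.zeros((100, 100), bool)
        mask[10:60, 10:80] = True  # 3500 px
        mask[80, 5:10] = True  # 5 px
        out = filter_blobs(mask, 3000)
        assert count_area(out) == 3500
        assert out[10:60, 10:80].all() and not out[80, 5:10].any()

    def test_everything_below_threshold_yields_empty_mask(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = mask[5, 5] = True
        assert not filter_blobs(mask, 2).any()

    def test_agrees_with_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            mask = rng.random((40, 40)) > 0.6
            min_area = int(rng.integers(1, 30))
            out = filter_blobs(mask, min_area)
            # subset of the input
            assert not (out & ~mask).any()
            # surviving components all reach min_area; removed area equals
            # the oracle's sum of small-component areas
            surviving = flood_fill_components(out)
            assert all(a >= min_area for a in surviving)
            all_areas = flood_fill_components(mask)
            assert count_area(out) == sum(a for a in all_areas if a >= min_area)


class TestFillHoles:
    def test_solid_square_unchanged(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        assert np.array_equal(fill_holes(mask), mask)

    def test_ring_becomes_solid_disc(self):
        mask = np.zeros((11, 11), bool)
        mask[2:9, 2:9] = True
        mask[3:8, 3:8] = False  # enclosed hole
        out = fill_holes(mask)
        assert out[2:9, 2:9].all()
        assert count_area(out) == 49

    def test_bay_open_to_border_not_filled(self):
        mask = np.ones((10, 10), bool)
        mask[0:6, 4:6] = False  # bay reaching the top border
        out = fill_holes(mask)
        assert not out[0:6, 4:6].any()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(mask=hnp.arrays(bool, (16, 16)))
    def test_idempotent_and_superset(self, mask):
        once = fill_holes(mask)
        assert np.array_equal(fill_holes(once), once)
        assert (once | mask == once).all()


class TestProcessFrame:
    def test_recovers_synthetic_silhouette_area_within_5_percent(self, config):
        frame, truth = render_scene(SceneSpec(seed=3))
        result = process_frame(frame, config)
        assert truth.area_pixels > 3000
        rel_err = abs(result.area_pixels - truth.area_pixels) / truth.area_pixels
        assert rel_err <= 0.05

    def test_swimmer_above_waterline_reports_zero_with_warning(self, config, small_swimmer):
        frame, _ = render_scene(
            SceneSpec(seed=1, swimmer=small_swimmer, reflection_enabled=False)
        )
        result = process_frame(frame, config)
        assert result.area_pixels == 0
        assert result.warnings

    def test_pure_water_scene_reports_zero_with_warning(self, config):
        frame, truth = render_scene(SceneSpec(seed=2, swimmer=None))
        assert truth.area_pixels == 0
        result = process_frame(frame, config)
        assert result.area_pixels == 0
        assert result.warnings

    def test_area_equals_final_mask_pixel_count(self, config, scene):
        frame, _ = scene
        result = process_frame(frame, config)
        assert result.area_pixels == count_area(result.final_mask)

    def test_enlarging_the_swimmer_never_shrinks_the_estimate(self, config):
        for seed in range(20):
            small = process_frame(
                render_scene(SceneSpec(seed=seed), scale=1.0)[0], config
            ).area_pixels
            large = process_frame(
                render_scene(SceneSpec(seed=seed), scale=1.08)[0], config
            ).area_pixels
            assert large >= small
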