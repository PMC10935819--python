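"""Mask refinement: binarization, line removal, dilation, flood-fill update,
size filtering, region extraction and cropping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import label as sk_label

from chemseg.refine import (
    RefineConfig,
    binarize_image,
    crop_structures,
    dilate_mask,
    extract_regions,
    filter_small_regions,
    random_erode,
    refine_mask,
    remove_straight_lines,
    scaled_min_region,
    threshold_prob_mask,
    update_mask,
)


@pytest.fixture()
def cfg():
    return RefineConfig()


class TestBinarize:
    def test_uniform_white_page_has_no_ink(self):
        assert binarize_image(np.full((8, 8), 255.0)).sum() == 0

    def test_two_by_two_example(self):
        page = np.array([[0, 255], [255, 255]], dtype=float)
        np.testing.assert_array_equal(
            binarize_image(page), np.array([[1, 0], [0, 0]], dtype=np.uint8)
        )

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(0)
        page = rng.integers(0, 230, size=(32, 32)).astype(float)
        np.testing.assert_array_equal(
            binarize_image(page), binarize_image(page + 20.0)
        )

    def test_color_page_rejected(self):
        with pytest.raises(ValueError):
            binarize_image(np.zeros((4, 4, 3)))


class TestLineRemoval:
    def test_blank_mask_unchanged(self, cfg):
        blank = np.zeros((64, 64), np.uint8)
        np.testing.assert_array_equal(remove_straight_lines(blank, cfg), blank)

    def test_full_width_line_removed_blob_kept(self, cfg):
        mask = np.zeros((512, 512), np.uint8)
        mask[100:102, :] = 1
        mask[200:230, 200:230] = 1
        out = remove_straight_lines(mask, cfg)
        assert out[100:102, :].sum() == 0
        assert out[200:230, 200:230].sum() == 900

    def test_vertical_line_removed(self, cfg):
        mask = np.zeros((512, 512), np.uint8)
        mask[:, 300:302] = 1
        assert remove_straight_lines(mask, cfg).sum() == 0

    def test_diagonal_line_untouched(self, cfg):
        mask = np.zeros((512, 512), np.uint8)
        idx = np.arange(512)
        mask[idx, idx] = 1
        np.testing.assert_array_equal(remove_straight_lines(mask, cfg), mask)

    def test_never_adds_pixels(self, cfg):
        rng = np.random.default_rng(1)
        mask = (rng.random((128, 128)) < 0.2).astype(np.uint8)
        out = remove_straight_lines(mask, cfg)
        assert not np.any(out & ~mask)


class TestDilation:
    def test_empty_mask_stays_empty(self, cfg):
        assert dilate_mask(np.zeros((64, 64), np.uint8), cfg).sum() == 0

    def test_single_pixel_becomes_kernel_block(self, cfg):
        mask = np.zeros((64, 64), np.uint8)
        mask[20, 20] = 1
        out = dilate_mask(mask, cfg)  # 3x3 kernel at this size
        assert out.sum() == 9
        assert out[19:22, 19:22].all()

    def test_nearby_pixels_connect(self, cfg):
        mask = np.zeros((64, 64), np.uint8)
        mask[10, 10] = mask[10, 12] = 1
        out = dilate_mask(mask, cfg)
        assert sk_label(out, connectivity=2).max() == 1

    def test_monotone_superset(self, cfg):
        rng = np.random.default_rng(2)
        mask = (rng.random((100, 90)) < 0.1).astype(np.uint8)
        out = dilate_mask(mask, cfg)
        assert np.all(out >= mask)

    def test_kernel_scales_with_size(self, cfg):
        mask = np.zeros((512, 512), np.uint8)
        mask[100, 100] = 1
        assert dilate_mask(mask, cfg).sum() == 25  # 5x5 kernel at 512


class TestThreshold:
    def test_zero_map_empty_mask(self, cfg):
        assert threshold_prob_mask(np.zeros((8, 8)), cfg).sum() == 0

    def test_exact_threshold_kept(self, cfg):
        prob = np.full((4, 4), cfg.prob_threshold)
        assert threshold_prob_mask(prob, cfg).all()

    def test_matches_loop_oracle(self, cfg):
        rng = np.random.default_rng(3)
        prob = rng.random((16, 16))
        got = threshold_prob_mask(prob, cfg)
        for r in range(16):
            for c in range(16):
                assert got[r, c] == (1 if prob[r, c] >= cfg.prob_threshold else 0)

    def test_out_of_range_rejected(self, cfg):
        with pytest.raises(ValueError):
            threshold_prob_mask(np.full((4, 4), 1.5), cfg)


def update_mask_oracle(ink, seed, connectivity=8):
    """Brute-force: label ink components, keep those intersecting the seed."""
    labels = sk_label(ink > 0, connectivity=2 if connectivity == 8 else 1)
    keep = set(np.unique(labels[seed > 0])) - {0}
    return np.isin(labels, sorted(keep)).astype(np.uint8)


class TestUpdateMask:
    def test_empty_seed_gives_empty_output(self, cfg):
        ink = np.ones((16, 16), np.uint8)
        assert update_mask(ink, np.zeros_like(ink), cfg).sum() == 0

    def test_partial_seed_recovers_touched_blob_only(self, cfg):
        ink = np.zeros((64, 64), np.uint8)
        ink[5:15, 5:15] = 1
        ink[40:50, 40:50] = 1
        seed = np.zeros_like(ink)
        seed[5:10, 5:15] = 1  # half of blob 1
        out = update_mask(ink, seed, cfg)
        assert out[5:15, 5:15].sum() == 100
        assert out[40:50, 40:50].sum() == 0

    def test_seed_on_background_deleted(self, cfg):
        ink = np.zeros((32, 32), np.uint8)
        ink[2:6, 2:6] = 1
        seed = np.zeros_like(ink)
        seed[20:25, 20:25] = 1
        assert update_mask(ink, seed, cfg).sum() == 0

    def test_idempotent(self, cfg):
        rng = np.random.default_rng(4)
        ink = (rng.random((48, 48)) < 0.3).astype(np.uint8)
        seed = (rng.random((48, 48)) < 0.05).astype(np.uint8)
        once = update_mask(ink, seed, cfg)
        np.testing.assert_array_equal(update_mask(ink, once, cfg), once)

    def test_shape_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError):
            update_mask(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8), cfg)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle_on_random_instances(self, seed_int):
        cfg = RefineConfig()
        rng = np.random.default_rng(seed_int)
        ink = (rng.random((32, 32)) < rng.uniform(0.1, 0.5)).astype(np.uint8)
        seed = (rng.random((32, 32)) < rng.uniform(0.02, 0.2)).astype(np.uint8)
        np.testing.assert_array_equal(
            update_mask(ink, seed, cfg), update_mask_oracle(ink, seed)
        )


class TestSizeFilter:
    def test_area_scaled_threshold(self, cfg):
        assert scaled_min_region((512, 512), cfg) == 400
        assert scaled_min_region((1024, 1024), cfg) == 1600

    def test_1599_component_removed_at_1024(self, cfg):
        mask = np.zeros((1024, 1024), np.uint8)
        mask[0:41, 0:39] = 1   # 1599 px
        assert mask.sum() == 1599
        assert filter_small_regions(mask, cfg).sum() == 0

    def test_empty_input(self, cfg):
        assert filter_small_regions(np.zeros((64, 64), np.uint8), cfg).sum() == 0

    def test_idempotent_and_never_adds(self, cfg):
        rng = np.random.default_rng(5)
        mask = (rng.random((512, 512)) < 0.4).astype(np.uint8)
        once = filter_small_regions(mask, cfg)
        assert not np.any(once & ~mask)
        np.testing.assert_array_equal(filter_small_regions(once, cfg), once)


class TestRegions:
    def test_empty_mask_no_regions(self, cfg):
        assert extract_regions(np.zeros((32, 32), np.uint8), cfg) == []

    def test_two_blocks_two_regions_sorted(self, cfg):
        mask = np.zeros((64, 64), np.uint8)
        mask[40:50, 5:15] = 1
        mask[5:15, 40:50] = 1
        regions = extract_regions(mask, cfg)
        assert [r.pixel_count for r in regions] == [100, 100]
        assert regions[0].bbox == (5, 40, 15, 50)
        assert regions[1].bbox == (40, 5, 50, 15)

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[2, 2] = mask[3, 3] = 1
        assert len(extract_regions(mask, RefineConfig(connectivity=8))) == 1
        assert len(extract_regions(mask, RefineConfig(connectivity=4))) == 2

    def test_regions_partition_mask(self, cfg):
        rng = np.random.default_rng(6)
        mask = (rng.random((60, 60)) < 0.3).astype(np.uint8)
        regions = extract_regions(mask, cfg)
        rebuilt = np.zeros_like(mask)
        for r in regions:
            assert rebuilt[r.pixels[:, 0], r.pixels[:, 1]].sum() == 0  # disjoint
            rebuilt[r.pixels[:, 0], r.pixels[:, 1]] = 1
        np.testing.assert_array_equal(rebuilt, mask)


class TestCrops:
    def test_identity_crop(self):
        cfg = RefineConfig(crop_pad=0)
        page = np.random.default_rng(7).integers(0, 255, (64, 64, 3)).astype(np.uint8)
        mask = np.zeros((64, 64), np.uint8)
        mask[10:20, 10:20] = 1
        regions = extract_regions(mask, cfg)
        crops = crop_structures(page, regions, cfg)
        np.testing.assert_array_equal(crops[0], page[10:20, 10:20])

    def test_corner_crop_clipped(self):
        cfg = RefineConfig(crop_pad=5)
        page = np.zeros((64, 64), np.uint8)
        mask = np.zeros((64, 64), np.uint8)
        mask[0:4, 0:4] = 1
        crops = crop_structures(page, extract_regions(mask, cfg), cfg)
        assert crops[0].shape == (9, 9)  # pad clipped at the page corner

    def test_low_resolution_mask_coordinates_scaled(self):
        cfg = RefineConfig(crop_pad=0)
        page = np.zeros((128, 128), np.uint8)
        mask = np.zeros((64, 64), np.uint8)
        mask[10:20, 10:20] = 1
        crops = crop_structures(page, extract_regions(mask, cfg), cfg,
                                mask_shape=(64, 64))
        assert crops[0].shape == (20, 20)  # 2x scale back to page resolution


class TestFullRefinement:
    def test_perfect_seed_recovers_truth_exactly(self, ten_pages):
        for pair in ten_pages[:5]:
            refined = refine_mask(pair.page.astype(float), pair.mask.astype(float))
            np.testing.assert_array_equal(refined.mask, pair.mask)

    def test_random_erosion_removes_requested_fraction(self):
        rng = np.random.default_rng(8)
        mask = np.ones((50, 50), np.uint8)
        eroded = random_erode(mask, 0.30, rng)
        assert eroded.sum() == 2500 - 750
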