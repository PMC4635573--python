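"""Unit and property tests for the branch-region segmentation pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from spikescan.segmentation import (
    NoPanicleError,
    binarize,
    extract_branch_regions,
    fill_holes,
    label_components,
    morphological_open,
    otsu_threshold,
    remove_small_objects,
    to_gray,
)

from .oracles import (
    count_components_union_find,
    fill_holes_flood,
    otsu_brute_force,
    random_blob_mask,
)


def _rgb(*pixels):
    return np.array([pixels], dtype=np.uint8)


class TestToGray:
    @pytest.mark.parametrize(
        "pixel, expected",
        [
            ((90, 90, 90), 90),    # identical channels pass through
            ((0, 0, 255), 85),     # round(255/3)
            ((255, 255, 255), 255),
            ((1, 2, 2), 2),        # 5/3 rounds half-up to 2
            ((0, 1, 0), 0),        # 1/3 rounds down
        ],
    )
    def test_channel_mean(self, pixel, expected):
        assert to_gray(_rgb(pixel))[0, 0] == expected

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError, match="RGB"):
            to_gray(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="RGB"):
            to_gray(np.zeros((4, 4, 4), dtype=np.uint8))

    def test_shape_preserved(self):
        img = np.zeros((5, 7, 3), dtype=np.uint8)
        assert to_gray(img).shape == (5, 7)


class TestOtsu:
    def test_bimodal_matches_brute_force(self):
        img = np.array([[0, 0, 0, 255, 255]], dtype=np.uint8)
        assert otsu_threshold(img) == otsu_brute_force(img)

    def test_two_valued_image_separates_classes(self):
        img = np.array([[50] * 3 + [200] * 7], dtype=np.uint8)
        t = otsu_threshold(img)
        assert 50 <= t < 200
        assert t == otsu_brute_force(img)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((4, 4), 7, dtype=np.uint8))

    def test_tie_break_takes_smallest(self):
        # perfectly symmetric two-level histogram: every t in [10, 199]
        # yields the identical split, so the smallest must be returned
        img = np.array([[10] * 5 + [200] * 5], dtype=np.uint8)
        assert otsu_threshold(img) == 10

    @given(
        npst.arrays(
            np.uint8, st.tuples(st.integers(1, 6), st.integers(2, 30))
        ).filter(lambda a: np.unique(a).size >= 2)
    )
    def test_matches_brute_force_on_arbitrary_images(self, img):
        assert otsu_threshold(img) == otsu_brute_force(img)


class TestBinarize:
    def test_auto_picks_minority_class(self):
        img = np.array([[0, 0, 255, 255, 255]], dtype=np.uint8)
        fg = binarize(img, 127, polarity="auto")
        assert fg.sum() == 2 and fg[0, 0] and fg[0, 1]

    def test_dark_foreground_full_mask(self):
        img = np.full((3, 3), 40, dtype=np.uint8)
        assert binarize(img, 127, polarity="dark_foreground").all()

    def test_light_foreground(self):
        img = np.array([[10, 240]], dtype=np.uint8)
        fg = binarize(img, 127, polarity="light_foreground")
        assert not fg[0, 0] and fg[0, 1]

    def test_invalid_inputs(self):
        img = np.zeros((2, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            binarize(img, 300)
        with pytest.raises(ValueError):
            binarize(img, 100, polarity="sideways")


class TestOpening:
    def test_one_pixel_line_vanishes(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 1:8] = True
        assert not morphological_open(mask).any()

    def test_solid_square_loses_only_corners(self):
        # a square is not open under the diamond: exactly its four corner
        # pixels (which no translated diamond inside the square covers)
        # are removed; the rest survives intact
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        opened = morphological_open(mask)
        diff = mask & ~opened
        assert set(map(tuple, np.argwhere(diff))) == {(2, 2), (2, 11), (11, 2), (11, 11)}

    def test_diamond_dilated_blob_is_invariant(self):
        # unions of translated structuring elements are exactly the
        # fixed points of opening
        from scipy import ndimage as ndi
        from skimage.morphology import disk

        mask = np.zeros((16, 16), dtype=bool)
        mask[4:10, 3:12] = True
        mask = ndi.binary_dilation(mask, structure=disk(1))
        assert np.array_equal(morphological_open(mask), mask)

    def test_idempotent_and_anti_extensive(self, rng):
        for _ in range(25):
            mask = random_blob_mask(rng)
            opened = morphological_open(mask)
            assert not (opened & ~mask).any()  # anti-extensive
            assert np.array_equal(morphological_open(opened), opened)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            morphological_open(np.ones((3, 3), dtype=bool), radius=0)


class TestFillHoles:
    def test_ring_becomes_solid(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        mask[3:7, 3:7] = False
        filled = fill_holes(mask)
        assert filled[2:8, 2:8].all()

    def test_no_hole_is_identity(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:4, 1:4] = True
        assert np.array_equal(fill_holes(mask), mask)

    def test_matches_flood_fill_oracle_and_is_extensive(self, rng):
        for _ in range(25):
            mask = random_blob_mask(rng)
            filled = fill_holes(mask)
            assert np.array_equal(filled, fill_holes_flood(mask))
            assert not (mask & ~filled).any()  # extensive
            assert np.array_equal(fill_holes(filled), filled)  # idempotent

    def test_leaves_no_enclosed_background(self, rng):
        mask = random_blob_mask(rng, n_blobs=6)
        filled = fill_holes(mask)
        # every remaining background pixel must be flood-reachable
        assert np.array_equal(fill_holes_flood(filled), filled)


class TestRemoveSmall:
    def test_99_pixel_blob_removed_at_default_cutoff(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:12, 1:10] = True  # 99 px
        assert mask.sum() == 99
        assert not remove_small_objects(mask, 100).any()

    def test_100_pixel_blob_kept(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:11, 1:11] = True  # exactly 100 px
        assert np.array_equal(remove_small_objects(mask, 100), mask)

    def test_only_large_blob_survives(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[1:6, 1:11] = True     # 50 px
        mask[15:35, 10:35] = True  # 500 px
        out = remove_small_objects(mask, 100)
        assert out.sum() == 500 and out[20, 20] and not out[2, 2]

    def test_invalid_min_pixels(self):
        with pytest.raises(ValueError):
            remove_small_objects(np.ones((3, 3), dtype=bool), 0)


class TestLabel:
    def test_empty_mask(self):
        labels, n = label_components(np.zeros((5, 5), dtype=bool))
        assert n == 0 and not labels.any()

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        _, n = label_components(mask)
        assert n == 1

    def test_labels_dense_and_count_matches_union_find(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng, shape=(25, 25))
            labels, n = label_components(mask)
            assert n == count_components_union_find(mask)
            assert set(np.unique(labels)) == set(range(n + 1))


class TestPipeline:
    def test_monotonic_stages_and_conservation(self, noisy_panicle):
        _, img, _ = noisy_panicle
        res = extract_branch_regions(img, keep_steps=True)
        b, o, f, c = (res.steps[k] for k in ("bin", "open", "fill", "clean"))
        assert not (o & ~b).any()  # opening shrinks
        assert not (o & ~f).any()  # filling grows
        assert not (c & ~f).any()  # cleanup shrinks
        # conservation: labeled pixels == final foreground pixels
        assert (res.labels > 0).sum() == c.sum()
        # overlay codes: 0 background, 1 discarded, 2 retained
        assert set(np.unique(res.steps["overlay"])) <= {0, 1, 2}

    def test_synthetic_branch_count_recovered(self, noisy_panicle):
        _, img, truth = noisy_panicle
        res = extract_branch_regions(img)
        assert res.n_regions == len(truth.branches)

    def test_blank_scan_raises(self):
        blank = np.full((60, 60, 3), 255, dtype=np.uint8)
        with pytest.raises(NoPanicleError):
            extract_branch_regions(blank)

    def test_dust_specks_are_cleaned_away(self, clean_panicle):
        _, img, truth = clean_panicle
        dusty = img.copy()
        for k in range(8):  # <100 px specks of dark dust in the empty border
            dusty[2:5, 5 + 12 * k : 8 + 12 * k] = 30
        res = extract_branch_regions(dusty)
        assert res.n_regions == len(truth.branches)
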