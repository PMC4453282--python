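"""Segmentation and RONI detection, checked against brute-force oracles."""

import numpy as np
import pytest

from sili.errors import EmptyBandError, SegmentationError
from sili.segmentation import (
    detect_roni,
    extract_lobes,
    remove_border_artifacts,
    threshold_lungs,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of scipy/skimage)
# ---------------------------------------------------------------------------

def flood_components(mask):
    """8-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not labels[rr, cc]):
                        labels[rr, cc] = current
                        stack.append((rr, cc))
    return labels, current


def brute_border_removal(mask):
    labels, n = flood_components(mask)
    out = np.asarray(mask, dtype=bool).copy()
    for comp in range(1, n + 1):
        m = labels == comp
        if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
            out &= ~m
    return out


# ---------------------------------------------------------------------------
# threshold_lungs
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_covers_dark_classes_on_phantom(self, phantom7):
        mask = threshold_lungs(phantom7.image)
        lungs = phantom7.lung_mask
        # essentially all ground-truth lung pixels are below threshold
        assert mask[lungs].mean() > 0.99
        # essentially no bright body tissue is
        body = phantom7.image > 150
        assert mask[body].mean() < 0.01

    def test_lsb_invariance_full_flip(self, phantom7):
        assert np.array_equal(threshold_lungs(phantom7.image),
                              threshold_lungs(phantom7.image ^ 1))

    def test_lsb_invariance_random_subset(self, phantom7):
        rng = np.random.default_rng(0)
        flip = (rng.random(phantom7.image.shape) < 0.3).astype(np.uint8)
        assert np.array_equal(threshold_lungs(phantom7.image),
                              threshold_lungs(phantom7.image ^ flip))

    def test_constant_image_fails(self):
        with pytest.raises(SegmentationError):
            threshold_lungs(np.full((64, 64), 128, dtype=np.uint8))

    def test_lsb_only_image_is_constant_after_masking(self):
        # values 128 and 129 differ only in bit 0 -> still no threshold
        img = np.full((64, 64), 128, dtype=np.uint8)
        img[::2] = 129
        with pytest.raises(SegmentationError):
            threshold_lungs(img)


# ---------------------------------------------------------------------------
# remove_border_artifacts
# ---------------------------------------------------------------------------

class TestBorderRemoval:
    def test_full_frame_removed(self):
        assert not remove_border_artifacts(np.ones((10, 12), dtype=bool)).any()

    def test_empty_mask_unchanged(self):
        assert not remove_border_artifacts(np.zeros((10, 12), dtype=bool)).any()

    def test_interior_ellipses_survive_border_component(self):
        mask = np.zeros((40, 60), dtype=bool)
        rr, cc = np.ogrid[:40, :60]
        mask |= ((rr - 20) / 8.0) ** 2 + ((cc - 18) / 7.0) ** 2 <= 1
        mask |= ((rr - 20) / 8.0) ** 2 + ((cc - 42) / 7.0) ** 2 <= 1
        mask[0, :] = True  # border-touching artifact
        mask[:, 0] = True
        cleaned = remove_border_artifacts(mask)
        assert np.array_equal(cleaned, brute_border_removal(mask))
        _, n = flood_components(cleaned)
        assert n == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((24, 24)) < 0.35
        assert np.array_equal(remove_border_artifacts(mask),
                              brute_border_removal(mask))


# ---------------------------------------------------------------------------
# extract_lobes
# ---------------------------------------------------------------------------

class TestExtractLobes:
    def test_two_largest_kept_small_discarded(self):
        mask = np.zeros((50, 100), dtype=bool)
        mask[10:35, 10:30] = True  # 500 px
        mask[10:30, 60:80] = True  # 400 px
        mask[45:46, 45:48] = True  # 3 px speck
        left, right = extract_lobes(mask)
        assert left.size == 500 and right.size == 400
        assert left.col_min == 10 and right.col_min == 60

    def test_left_right_by_centroid_column(self):
        mask = np.zeros((30, 100), dtype=bool)
        mask[5:15, 70:90] = True
        mask[5:15, 10:30] = True
        left, right = extract_lobes(mask)
        assert left.col_max < right.col_min

    def test_equal_sizes_tiebreak_is_deterministic(self):
        mask = np.zeros((30, 100), dtype=bool)
        mask[5:15, 10:20] = True
        mask[5:15, 40:50] = True
        mask[5:15, 70:80] = True  # three equal components; leftmost two win
        left, right = extract_lobes(mask)
        assert (left.col_min, right.col_min) == (10, 40)

    def test_single_component_fails(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:10, 5:10] = True
        with pytest.raises(SegmentationError):
            extract_lobes(mask)


# ---------------------------------------------------------------------------
# detect_roni
# ---------------------------------------------------------------------------

class TestDetectRoni:
    def test_rectangular_lobes_band_enumerated(self, rect_roni):
        # lobes rows 20..80 at cols 10..40 / 60..90 -> band rows 20..80,
        # cols 41..59: 61 * 19 = 1159 pixels, none of them lobe pixels
        assert rect_roni.size_host_logo == 61 * 19 == 1159
        band = set(map(tuple, rect_roni.interlobe_pixels))
        expected = {(r, c) for c in range(41, 60) for r in range(20, 81)}
        assert band == expected

    def test_column_major_ordering(self, rect_roni):
        for coords in (rect_roni.interlobe_pixels, rect_roni.surround_pixels):
            keys = coords[:, 1].astype(np.int64) * 10**6 + coords[:, 0]
            assert (np.diff(keys) > 0).all()

    def test_partition_covers_image(self, roni7):
        total = roni7.shape[0] * roni7.shape[1]
        assert (roni7.roi_mask.sum() + roni7.size_host_logo
                + roni7.size_host_index) == total
        # pairwise disjoint: no listed pixel is inside the ROI
        for coords in (roni7.interlobe_pixels, roni7.surround_pixels):
            assert not roni7.roi_mask[coords[:, 0], coords[:, 1]].any()
        band = set(map(tuple, roni7.interlobe_pixels))
        surround = set(map(tuple, roni7.surround_pixels))
        assert not band & surround

    def test_band_matches_phantom_mediastinum(self, phantom7, roni7):
        """The detected band sits between the generator's lung ellipses."""
        left_cols = np.nonzero(phantom7.left_lung.any(axis=0))[0]
        right_cols = np.nonzero(phantom7.right_lung.any(axis=0))[0]
        band_cols = np.unique(roni7.interlobe_pixels[:, 1])
        assert band_cols.min() >= left_cols.max()
        assert band_cols.max() <= right_cols.min()

    def test_full_lsb_flip_gives_identical_map(self, phantom7, roni7):
        other = detect_roni(phantom7.image ^ 1)
        assert np.array_equal(other.roi_mask, roni7.roi_mask)
        assert np.array_equal(other.interlobe_pixels, roni7.interlobe_pixels)
        assert np.array_equal(other.surround_pixels, roni7.surround_pixels)

    def test_touching_lobes_give_empty_band_error(self):
        img = np.full((100, 100), 200, dtype=np.uint8)
        img[20:81, 10:50] = 20
        img[30:91, 50:90] = 20  # shares column 49/50 boundary: no gap
        with pytest.raises((EmptyBandError, SegmentationError)):
            detect_roni(img)
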