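"""Unit tests for the four-stage counting pipeline."""

import numpy as np
import pytest
from scipy import stats

from nucleocount.core import (
    BinaryMask,
    GrayscaleImage,
    NoObjectsError,
    binarize,
    compute_otsu_threshold,
    count_from_areas,
    count_image,
    label_objects,
    to_grayscale,
    trimmed_mean_area,
)

from _oracles import flood_fill_label, otsu_bruteforce, roundsum_bruteforce


class TestToGrayscale:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (np.full((4, 5), 255, dtype=np.uint8), 1.0),
            (np.full((4, 5, 3), 255, dtype=np.uint8), 1.0),
            (np.full((4, 5), 51, dtype=np.uint8), 0.2),
            (np.full((2, 2), 65535, dtype=np.uint16), 1.0),
        ],
    )
    def test_uniform_rescaling(self, raw, expected):
        img = to_grayscale(raw)
        assert img.pixels == pytest.approx(np.full((raw.shape[0], raw.shape[1]), expected))

    def test_rgb_luma_weights(self):
        """A pure-blue pixel collapses to the blue luma weight 0.1140.

        Weights are normalized to sum to 1 (so white maps to exactly
        1.0), shifting the blue coefficient by ~1e-5.
        """
        raw = np.zeros((1, 1, 3), dtype=np.uint8)
        raw[0, 0, 2] = 255
        assert to_grayscale(raw).pixels[0, 0] == pytest.approx(0.1140, abs=2e-4)

    @pytest.mark.parametrize(
        "raw, kwargs",
        [
            (np.zeros((3, 3, 2), dtype=np.uint8), {}),          # 2 channels
            (np.zeros((3, 3, 3, 1), dtype=np.uint8), {}),       # 4-D
            (np.zeros((3, 3), dtype=np.uint8), {"bit_depth": 12}),
            (np.zeros((3, 3), dtype=np.int32), {}),             # no inferable depth
            (np.zeros((0, 3), dtype=np.uint8), {}),             # empty
        ],
    )
    def test_rejects_unsupported_input(self, raw, kwargs):
        with pytest.raises(ValueError):
            to_grayscale(raw, **kwargs)


class TestOtsuThreshold:
    def test_separates_two_populations(self):
        px = np.full((10, 10), 0.2)
        px[:, 5:] = 0.8
        t = compute_otsu_threshold(GrayscaleImage(px))
        assert 0.2 <= t < 0.8
        assert binarize(GrayscaleImage(px), t).pixels.sum() == 50

    def test_constant_image_degenerates_to_own_level(self):
        img = GrayscaleImage(np.full((8, 8), 0.5))
        t = compute_otsu_threshold(img)
        assert t == 0.5
        assert binarize(img, t).pixels.sum() == 0

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(25):
            raw = rng.integers(0, 256, (64, 64), dtype=np.uint8)
            img = to_grayscale(raw)
            assert compute_otsu_threshold(img) == otsu_bruteforce(img.pixels)


class TestBinarize:
    def test_level_one_yields_empty_mask(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (16, 16)))
        assert binarize(img, 1.0).pixels.sum() == 0

    def test_level_zero_sets_all_positive_pixels(self, rng):
        img = GrayscaleImage(rng.uniform(0.01, 1, (16, 16)))
        assert binarize(img, 0.0).pixels.all()

    def test_pixels_at_level_go_to_background(self):
        img = GrayscaleImage(np.array([[0.5, 0.5001], [0.4999, 0.5]]))
        assert binarize(img, 0.5).pixels.tolist() == [[0, 1], [0, 0]]

    @pytest.mark.parametrize("level", [-0.1, 1.1])
    def test_rejects_out_of_range_level(self, level):
        with pytest.raises(ValueError):
            binarize(GrayscaleImage(np.zeros((2, 2))), level)


class TestLabelObjects:
    def test_empty_mask_gives_empty_table(self):
        table = label_objects(BinaryMask(np.zeros((5, 5), dtype=np.uint8)))
        assert len(table) == 0
        assert table.label_map.sum() == 0

    def test_two_squares_labeled_left_to_right(self):
        mask = np.zeros((10, 20), dtype=np.uint8)
        mask[1:4, 12:15] = 1   # right square stamped first in memory order
        mask[5:8, 2:5] = 1     # left square
        table = label_objects(BinaryMask(mask))
        assert table.areas.tolist() == [9, 9]
        assert table.centroid_cols.tolist() == [3.0, 13.0]
        assert table.centroid_rows.tolist() == [6.0, 2.0]
        assert table.labels.tolist() == [1, 2]
        assert table.label_map[6, 3] == 1 and table.label_map[2, 13] == 2

    def test_matches_flood_fill_oracle_on_random_rectangles(self, rng):
        mask = np.zeros((120, 120), dtype=np.uint8)
        stamped = 0
        while stamped < 40:
            r, c = rng.integers(0, 110, 2)
            h, w = rng.integers(2, 8, 2)
            region = (slice(max(r - 1, 0), r + h + 1), slice(max(c - 1, 0), c + w + 1))
            if mask[region].any():
                continue
            mask[r : r + h, c : c + w] = 1
            stamped += 1
        table = label_objects(BinaryMask(mask))
        oracle = flood_fill_label(mask)
        assert len(table) == len(oracle) == 40
        assert sorted(table.areas) == sorted(o["area"] for o in oracle)
        key = lambda rc: (round(rc[1], 9), round(rc[0], 9))
        got = sorted(zip(table.centroid_rows, table.centroid_cols), key=key)
        want = sorted(((o["centroid_row"], o["centroid_col"]) for o in oracle), key=key)
        assert got == pytest.approx(want)

    def test_area_sum_equals_foreground_pixels(self, rng):
        mask = (rng.uniform(0, 1, (64, 64)) > 0.6).astype(np.uint8)
        table = label_objects(BinaryMask(mask))
        assert table.areas.sum() == mask.sum()
        assert (table.label_map > 0).sum() == mask.sum()


class TestTrimmedMean:
    def test_constant_array_is_invariant(self):
        assert trimmed_mean_area([100, 100, 100], 10) == 100.0
        assert trimmed_mean_area([100, 100, 100], 50) == 100.0

    def test_ten_percent_trim_drops_five_outliers_per_tail(self):
        areas = [100] * 90 + [1] * 5 + [10000] * 5
        assert trimmed_mean_area(areas, 10) == 100.0

    def test_matches_scipy_trim_mean(self, rng):
        for trim in (0, 10, 25):
            areas = rng.integers(1, 500, 83)
            assert trimmed_mean_area(areas, trim) == pytest.approx(
                stats.trim_mean(areas, trim / 200.0), rel=1e-12
            )

    def test_small_n_degrades_to_plain_mean(self):
        areas = [1, 2, 30]  # k = floor(3 * 10 / 200) = 0
        assert trimmed_mean_area(areas, 10) == pytest.approx(11.0)

    def test_empty_input_raises_no_objects(self):
        with pytest.raises(NoObjectsError):
            trimmed_mean_area([], 10)

    @pytest.mark.parametrize("trim", [-1, 100])
    def test_rejects_bad_trim_percent(self, trim):
        with pytest.raises(ValueError):
            trimmed_mean_area([1.0], trim)


class TestCountFromAreas:
    @pytest.mark.parametrize(
        "areas, mean, expected",
        [
            ([10, 10, 10], 10.0, 3),       # all ratios exactly 1
            ([160], 100.0, 2),             # ratio 1.6 -> 2 cells
            ([40], 100.0, 0),              # ratio 0.4 -> discarded
            ([150], 100.0, 2),             # ratio exactly 1.5 rounds up
            ([50], 100.0, 1),              # ratio exactly 0.5 rounds up
            ([250], 100.0, 3),             # 2.5 rounds away from zero, not to even
            ([49], 100.0, 0),
        ],
    )
    def test_ratio_rounding_rules(self, areas, mean, expected):
        assert count_from_areas(areas, mean) == expected

    def test_matches_elementwise_oracle(self, rng):
        areas = rng.integers(1, 1000, 1000)
        assert count_from_areas(areas, 137.0) == roundsum_bruteforce(areas, 137.0)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            count_from_areas([10], 0.0)


class TestCountImage:
    def test_uniform_background_counts_zero(self, caplog):
        img = GrayscaleImage(np.full((32, 32), 0.05))
        with caplog.at_level("WARNING", logger="nucleocount.core"):
            result = count_image(img, image_id="blank")
        assert result.total_count == 0
        assert result.n_objects == 0
        assert result.mean_nucleus_area is None
        assert any("no foreground" in m for m in caplog.messages)

    def test_disjoint_equal_nuclei_count_exactly(self):
        img_px = np.full((60, 60), 0.05)
        for r in range(5, 60, 12):
            for c in range(5, 60, 12):
                img_px[r : r + 4, c : c + 4] = 0.9
        result = count_image(GrayscaleImage(img_px))
        assert result.n_objects == 25
        assert result.total_count == 25
        assert result.mean_nucleus_area == pytest.approx(16.0)

    def test_double_area_object_counts_twice(self):
        img_px = np.full((40, 120), 0.05)
        for c in range(5, 95, 10):
            img_px[5:9, c : c + 4] = 0.9       # nine 16-px singlets
        img_px[20:24, 20:28] = 0.9             # one 32-px "doublet"
        result = count_image(GrayscaleImage(img_px))
        assert result.n_objects == 10
        assert result.total_count == 11
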