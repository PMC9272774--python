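"""Strip search, balance-function refinement and multi-ROI sliding."""

import numpy as np
import pytest

from tasselrow import (
    BoundingBox,
    ConfigError,
    DetectionError,
    NoCropRowError,
    RoiStatus,
    SceneParams,
    TrackerParams,
    balance_function,
    extract_multi_roi,
    find_initial_box,
    generate_mask_scene,
    slide_and_classify,
    split_strips,
    update_box,
)
from tasselrow.roi_tracker import (
    balance_curve,
    box_column_profile,
    strip_column_counts,
    white_count,
)


def _balance_bruteforce(Z, xp):
    il = sum(Z[v] * (xp - v) for v in range(xp + 1))
    ir = sum(Z[v] * (v - xp) for v in range(xp + 1, len(Z)))
    return abs(il - ir)


def _blob(mask, x, y, w=20, h=20):
    mask[max(0, y - h) : y, max(0, x - w // 2) : x + w // 2] = 255


class TestSplitStrips:
    def test_default_geometry(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        left, right, strips = split_strips(mask, tp)
        assert left == (0, 260) and right == (260, 600)
        assert len(strips) == 8
        assert strips[0] == (580, 600)  # K1 at the bottom
        assert strips[-1] == (440, 460)

    def test_single_strip(self):
        mask = np.zeros((600, 600), np.uint8)
        _, _, strips = split_strips(mask, TrackerParams(n_strips=1))
        assert strips == [(580, 600)]

    def test_strips_exceeding_image_rejected(self):
        mask = np.zeros((600, 600), np.uint8)
        with pytest.raises(ConfigError):
            split_strips(mask, TrackerParams(delta_h=300, n_strips=8))

    def test_center_outside_image_rejected(self):
        mask = np.zeros((100, 100), np.uint8)
        with pytest.raises(ConfigError):
            split_strips(mask, TrackerParams(center=260, n_strips=1))


class TestStripColumnCounts:
    def test_black_strip_zero(self):
        mask = np.zeros((600, 600), np.uint8)
        assert strip_column_counts(mask, (580, 600), (0, 260)).sum() == 0

    def test_full_white_column(self):
        mask = np.zeros((600, 600), np.uint8)
        mask[580:600, 42] = 255
        counts = strip_column_counts(mask, (580, 600), (0, 260))
        assert counts[42] == 20 and counts.sum() == 20

    def test_random_strip_matches_loop(self, rng):
        strip = (rng.random((20, 50)) < 0.4).astype(np.uint8) * 255
        mask = np.zeros((600, 600), np.uint8)
        mask[580:600, 100:150] = strip
        counts = strip_column_counts(mask, (580, 600), (100, 150))
        expected = [sum(strip[i, j] == 255 for i in range(20)) for j in range(50)]
        np.testing.assert_array_equal(counts, expected)


class TestFindInitialBox:
    def test_block_in_bottom_strip(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        _blob(mask, x=150, y=600)
        box = find_initial_box(mask, "left", tp)
        assert box.yr == 600
        assert abs(box.xr - 150) <= 10  # balance refinement centres on the block

    def test_anchor_row_from_third_strip(self, tp):
        # nothing qualifies in K1/K2; the K3 strip anchors at 600 − 2·Δh
        mask = np.zeros((600, 600), np.uint8)
        _blob(mask, x=150, y=560)
        box = find_initial_box(mask, "left", tp)
        assert box.yr == 560

    def test_column_closest_to_center_wins(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        _blob(mask, x=50, y=600)
        _blob(mask, x=200, y=600)
        box = find_initial_box(mask, "left", tp)
        assert abs(box.xr - 200) <= 10

    def test_no_qualifying_strip_raises(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        mask[590:600, 100] = 255  # max column count 10 < Y=15
        with pytest.raises(NoCropRowError):
            find_initial_box(mask, "left", tp)


class TestBalanceFunction:
    def test_zero_profile_flat(self):
        Z = np.zeros(30)
        assert all(balance_function(Z, xp) == 0 for xp in range(30))

    @pytest.mark.parametrize("v0,k", [(0, 3), (17, 5), (99, 20)])
    def test_single_spike_law(self, v0, k):
        Z = np.zeros(100)
        Z[v0] = k
        for xp in range(100):
            assert balance_function(Z, xp) == k * abs(xp - v0)

    def test_uniform_profile_matches_bruteforce(self):
        Z = np.ones(100)
        curve = [balance_function(Z, xp) for xp in range(100)]
        expected = [_balance_bruteforce(Z, xp) for xp in range(100)]
        assert curve == expected
        mid = int(np.argmin(curve))
        assert mid in (49, 50)

    def test_curve_equals_pointwise(self, rng):
        Z = rng.integers(0, 21, 80)
        np.testing.assert_allclose(
            balance_curve(Z), [balance_function(Z, xp) for xp in range(80)]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            balance_function(np.ones(10), 10)


class TestUpdateBox:
    def test_symmetric_block_centres(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        mask[580:600, 140:161] = 255  # symmetric about column 150
        box = BoundingBox.from_params(130, 600, tp)
        new, empty = update_box(mask, box, tp)
        assert not empty
        assert new.xr == 150 and new.yr == 600

    def test_single_column_spike(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        mask[580:600, 137] = 255
        box = BoundingBox.from_params(150, 600, tp)
        new, _ = update_box(mask, box, tp)
        assert new.xr == 137

    def test_empty_box_unchanged(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        box = BoundingBox.from_params(150, 600, tp)
        new, empty = update_box(mask, box, tp)
        assert empty and new == box

    def test_random_content_matches_bruteforce(self, tp, rng):
        for _ in range(25):
            mask = np.zeros((600, 600), np.uint8)
            content = (rng.random((20, 100)) < 0.3).astype(np.uint8) * 255
            mask[580:600, 100:200] = content
            box = BoundingBox.from_params(145, 600, tp)  # spans exactly [100, 200)
            new, empty = update_box(mask, box, tp)
            if empty:
                assert content.sum() == 0
                continue
            Z = [(content[:, j] == 255).sum() for j in range(100)]
            curve = [_balance_bruteforce(Z, xp) for xp in range(100)]
            assert new.xr - 100 == int(np.argmin(curve))

    def test_t1_equals_profile_sum(self, tp, rng):
        # cross-check of the two white-pixel counting routes
        for _ in range(10):
            mask = (rng.random((600, 600)) < 0.2).astype(np.uint8) * 255
            box = BoundingBox.from_params(
                int(rng.integers(50, 550)), int(rng.integers(30, 600)), tp
            )
            Z, _ = box_column_profile(mask, box)
            assert white_count(mask, box) == Z.sum()


class TestSlideAndClassify:
    def test_dense_region_is_feature(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        _blob(mask, x=150, y=580)
        prev = BoundingBox.from_params(150, 600, tp)
        box, status = slide_and_classify(mask, prev, tp)
        assert status is RoiStatus.FEATURE
        assert box.yr == 580 and abs(box.xr - 150) <= 10

    def test_sparse_region_shifts_toward_center(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        mask[565:580, 100] = 255  # 15 px at the prev anchor: sparse (< T0)
        _blob(mask, x=175, y=580)  # outside [55,155); dense after one d-shift
        prev = BoundingBox.from_params(100, 600, tp)
        box, status = slide_and_classify(mask, prev, tp)
        assert status is RoiStatus.SPARSE_CORRECTED
        assert box.xr > 100

    def test_lost_row_recorded_empty(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        prev = BoundingBox.from_params(150, 600, tp)
        box, status = slide_and_classify(mask, prev, tp)
        assert status is RoiStatus.EMPTY
        assert (box.xr, box.yr) == (150, 580)  # trend position kept

    def test_off_trend_blob_flagged_deviated(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        _blob(mask, x=150, y=580)  # 50 px right of the anchor trend at 100
        prev = BoundingBox.from_params(100, 600, tp)
        box, status = slide_and_classify(mask, prev, tp, trend=(100, 100))
        assert status is RoiStatus.DEVIATED
        assert box.xr == 100  # deviated level keeps the trend anchor

    def test_termination_above_image(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        prev = BoundingBox.from_params(100, 30, tp)
        assert slide_and_classify(mask, prev, tp) is None


class TestExtractMultiRoi:
    def test_clean_rows_tracked(self, clean_mask_scene, tp):
        mask, truth = clean_mask_scene
        left, right = extract_multi_roi(mask, tp)
        for chain, line in ((left, truth.left), (right, truth.right)):
            assert chain.found
            contributing = [
                (b, s) for b, s in chain.rois if s.contributes
            ]
            assert len(contributing) >= 600 // tp.delta_h - 2
            for box, _ in contributing:
                assert abs(box.xr - line.x_at(box.yr)) <= tp.L1

    def test_accepted_anchor_rows_step_by_delta_h(self, clean_mask_scene, tp):
        mask, _ = clean_mask_scene
        left, _ = extract_multi_roi(mask, tp)
        ys = [box.yr for box, _ in left.rois]
        assert np.all(np.diff(ys) == -tp.delta_h)

    def test_all_black_mask_fails(self, tp):
        with pytest.raises(DetectionError):
            extract_multi_roi(np.zeros((600, 600), np.uint8), tp)

    def test_one_sided_field(self, tp):
        mask = np.zeros((600, 600), np.uint8)
        for y in range(600, 40, -20):
            _blob(mask, x=150, y=y)
        left, right = extract_multi_roi(mask, tp)
        assert left.found and not right.found
        assert right.rois == []

    def test_deviated_blobs_excluded(self, tp):
        mask, truth = generate_mask_scene(
            SceneParams(seed=21, impulse_noise=0.0, deviated_blobs=2)
        )
        left, right = extract_multi_roi(mask, tp)
        for chain, line in ((left, truth.left), (right, truth.right)):
            for box in chain.contributing():
                assert abs(box.xr - line.x_at(box.yr)) <= tp.L1
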