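"""Detection: augmentation algebra, tiling, NMS, sliced inference, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qbrm.core import ParameterMap, render_rgb
from qbrm.detect import (
    GEOM_VARIANTS,
    BlobDetector,
    BoundingBox,
    Detection,
    GroundTruthDetector,
    MatchedFilterDetector,
    TilingConfig,
    TrainConfig,
    augment,
    color_rotate,
    crop_training_patches,
    invert_geom,
    iou,
    merge_consensus,
    nms,
    sliced_inference,
    tile_origins,
    train_reference_detector,
    transform_box,
    transform_patch,
)
from qbrm.stats import match_detections
from qbrm.synth import SectionSimConfig

from conftest import simulate_rgb


def box_strategy(size=128):
    return st.builds(
        lambda x, y, w, h: BoundingBox(
            min(x, size - w), min(y, size - h), w, h
        ),
        st.integers(0, size - 1),
        st.integers(0, size - 1),
        st.integers(1, size // 2),
        st.integers(1, size // 2),
    )


class TestColorRotation:
    def test_identity_and_group_of_order_three(self):
        img = np.random.default_rng(0).uniform(size=(8, 8, 3))
        assert np.array_equal(color_rotate(img, 0), img)
        assert np.array_equal(color_rotate(color_rotate(color_rotate(img, 1), 1), 1), img)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            color_rotate(np.zeros((8, 8)), 1)

    def test_matches_60_degree_orientation_shift_of_rendering(self):
        phi = np.arange(0.0, 180.0, 0.5).reshape(12, 30)
        ones, mask = np.ones_like(phi), np.ones_like(phi, bool)
        rendered = render_rgb(ParameterMap(ones, phi, mask))
        shifted = render_rgb(ParameterMap(ones, np.mod(phi + 60.0, 180.0), mask))
        assert np.array_equal(color_rotate(rendered, 1), shifted)


class TestConsensus:
    def test_identical_lists_survive(self):
        boxes = [BoundingBox(0, 0, 5, 5), BoundingBox(20, 20, 4, 6)]
        assert merge_consensus(boxes, list(boxes), 0.5) == boxes

    def test_disjoint_lists_give_empty_consensus(self):
        a = [BoundingBox(0, 0, 5, 5)]
        b = [BoundingBox(50, 50, 5, 5)]
        assert merge_consensus(a, b, 0.5) == []

    def test_single_agreeing_pair_averaged(self):
        a = [BoundingBox(0, 0, 10, 10), BoundingBox(40, 0, 5, 5), BoundingBox(0, 40, 5, 5)]
        # middle box overlaps a[0] with IoU 0.6: 10x10 vs shifted 10x10
        b = [BoundingBox(0, 2.5, 10, 10), BoundingBox(80, 80, 5, 5), BoundingBox(60, 20, 5, 5)]
        assert iou(a[0], b[0]) == pytest.approx(0.6)
        out = merge_consensus(a, b, 0.5)
        assert out == [BoundingBox(0, 1.25, 10, 10)]

    def test_matching_is_one_to_one_against_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        a = [BoundingBox(x, y, 6, 6) for x, y in rng.integers(0, 100, (15, 2))]
        b = [BoundingBox(x, y, 6, 6) for x, y in rng.integers(0, 100, (15, 2))]
        out = merge_consensus(a, b, 0.3)
        # oracle: exhaustive greedy over the IoU matrix
        pairs = sorted(
            ((iou(x, y), i, j) for i, x in enumerate(a) for j, y in enumerate(b)),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_a, used_b, n = set(), set(), 0
        for v, i, j in pairs:
            if v < 0.3:
                break
            if i not in used_a and j not in used_b:
                used_a.add(i)
                used_b.add(j)
                n += 1
        assert len(out) == n


class TestPatchesAndAugmentation:
    def test_image_equal_to_tile_yields_one_patch(self):
        out = crop_training_patches(np.zeros((128, 128, 3)), [], TilingConfig())
        assert len(out) == 1

    def test_256_with_half_overlap_yields_nine_patches(self):
        out = crop_training_patches(np.zeros((256, 256, 3)), [], TilingConfig())
        assert len(out) == 9  # ceil((256-128)/64)+1 = 3 per axis

    def test_box_shifts_by_patch_origin(self):
        box = BoundingBox(130, 140, 10, 10)
        out = crop_training_patches(np.zeros((256, 256, 3)), [box], TilingConfig())
        patches_with_box = [(b, o) for _, bs, o in out for b in bs if bs]
        assert (BoundingBox(2, 12, 10, 10), (128, 128)) in patches_with_box

    def test_mostly_clipped_box_dropped(self):
        box = BoundingBox(120, 0, 20, 20)  # 40% visible in the first patch
        patch, boxes, _ = crop_training_patches(
            np.zeros((128, 256, 3)), [box], TilingConfig()
        )[0]
        assert boxes == []

    @pytest.mark.parametrize("geom", GEOM_VARIANTS)
    def test_box_transform_agrees_with_pixel_mask_oracle(self, geom):
        rng = np.random.default_rng(1)
        size = 16
        for _ in range(20):
            x, y = rng.integers(0, 10, 2)
            w, h = rng.integers(1, size - max(x, y), 2)
            box = BoundingBox(int(x), int(y), int(w), int(h))
            mask = np.zeros((size, size))
            mask[box.y : int(box.y2), box.x : int(box.x2)] = 1
            warped = transform_patch(mask, geom)
            ys, xs = np.nonzero(warped)
            oracle = BoundingBox(
                xs.min(), ys.min(), xs.max() - xs.min() + 1, ys.max() - ys.min() + 1
            )
            assert transform_box(box, geom, size) == oracle

    @pytest.mark.parametrize("geom", GEOM_VARIANTS)
    def test_transform_inverse_round_trip(self, geom):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.integers(0, 100, 2)
            w, h = rng.integers(1, 28, 2)
            box = BoundingBox(int(x), int(y), int(w), int(h))
            there = transform_box(box, geom, 128)
            back = transform_box(there, invert_geom(geom), 128)
            assert back == box

    def test_identity_draw_leaves_patch_and_boxes_unchanged(self):
        patch = np.random.default_rng(0).uniform(size=(32, 32, 3))
        boxes = [BoundingBox(4, 5, 6, 7)]
        cfg = TrainConfig(augmentations=())
        out_patch, out_boxes = augment(patch, boxes, cfg, np.random.default_rng(0))
        assert np.array_equal(out_patch, patch)
        assert out_boxes == boxes

    def test_augmentation_preserves_box_count_and_areas(self):
        rng = np.random.default_rng(3)
        patch = rng.uniform(size=(64, 64, 3))
        boxes = [BoundingBox(2, 3, 10, 4), BoundingBox(30, 40, 7, 7)]
        for _ in range(25):
            _, out = augment(patch, boxes, TrainConfig(), rng)
            assert len(out) == len(boxes)
            assert sorted(b.area for b in out) == sorted(b.area for b in boxes)


class TestNMS:
    def test_empty_input(self):
        assert nms([], 0.5) == []

    def test_coincident_boxes_keep_highest_confidence(self):
        box = BoundingBox(10, 10, 5, 5)
        out = nms([Detection(box, 0.8), Detection(box, 0.9)], 0.5)
        assert [d.confidence for d in out] == [0.9]

    def test_disjoint_boxes_both_kept(self):
        dets = [
            Detection(BoundingBox(0, 0, 5, 5), 0.9),
            Detection(BoundingBox(50, 50, 5, 5), 0.8),
        ]
        assert len(nms(dets, 0.5)) == 2

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(box_strategy(), st.floats(0.01, 1.0)), max_size=20))
    def test_nms_is_idempotent(self, items):
        dets = [Detection(b, round(c, 3)) for b, c in items]
        once = nms(dets, 0.5)
        assert nms(once, 0.5) == once


class TestTiling:
    def test_every_pixel_covered_and_interior_four_fold(self):
        tiling = TilingConfig()
        cover = np.zeros((300, 420), int)
        for x, y in tile_origins(300, 420, tiling):
            cover[y : y + 128, x : x + 128] += 1
        assert cover.min() >= 1
        assert cover[140:160, 140:280].min() >= 4  # interior, 50% overlap

    def test_image_smaller_than_tile_rejected(self):
        with pytest.raises(ValueError):
            tile_origins(100, 300, TilingConfig())


class TestSlicedInference:
    def test_oracle_detector_recovers_ground_truth(self, small_section):
        _, truth, rgb = small_section
        assert len(truth.debris_boxes) >= 5
        oracle = GroundTruthDetector(truth.debris_boxes)
        result = sliced_inference(rgb, oracle, TilingConfig(), nms_iou=0.6)
        match = match_detections(result.detections, truth.debris_boxes, 0.9)
        assert len(match.pairs) == len(truth.debris_boxes)
        assert match.unmatched_pred == []

    def test_no_objects_no_detections(self):
        cfg = SectionSimConfig(
            image_height_px=256, image_width_px=256, debris_density_per_mm2=0.0, seed=1
        )
        truth, rgb = simulate_rgb(cfg)
        result = sliced_inference(rgb, GroundTruthDetector([]), TilingConfig())
        assert result.detections == []

    def test_tta_equals_plain_inference_for_equivariant_detector(self, small_section):
        # the blob detector commutes exactly with flips/rotations and is
        # color-blind, so every TTA variant yields the same global boxes
        _, _, rgb = small_section
        blob = BlobDetector(threshold=0.5)
        off = sliced_inference(rgb, blob, TilingConfig(), tta=False, confidence_thr=0.0)
        on = sliced_inference(rgb, blob, TilingConfig(), tta=True, confidence_thr=0.0)
        key = lambda d: (d.box.x, d.box.y, d.box.width, d.box.height, round(d.confidence, 9))
        assert sorted(map(key, off.detections)) == sorted(map(key, on.detections))

    def test_failing_tile_is_reported_not_fatal(self):
        class Flaky(BlobDetector):
            def predict(self, patch, origin=(0, 0)):
                if origin == (0, 0):
                    raise RuntimeError("camera glitch")
                return super().predict(patch, origin)

        rgb = np.zeros((256, 256, 3))
        result = sliced_inference(rgb, Flaky(), TilingConfig())
        assert len(result.failed_tiles) == 1
        assert "camera glitch" in result.failed_tiles[0][1]


class TestReferenceDetector:
    def test_blank_patch_yields_no_detections(self):
        detector = MatchedFilterDetector()
        assert detector.predict(np.zeros((128, 128, 3))) == []

    def test_training_is_deterministic(self, small_section):
        _, truth, rgb = small_section
        patches = [
            (p, b) for p, b, _ in crop_training_patches(rgb, truth.debris_boxes, TilingConfig())
        ]
        det_a, log_a = train_reference_detector(patches)
        det_b, log_b = train_reference_detector(patches)
        assert det_a == det_b
        assert log_a["operating_point"] == log_b["operating_point"]

    def test_training_without_positives_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            train_reference_detector([(np.zeros((128, 128, 3)), [])])

    def test_detects_most_debris_on_held_out_sections(self, trained_detector):
        detector, _ = trained_detector
        tp = n_det = n_gt = 0
        for seed in (77, 78, 79, 80):
            cfg = SectionSimConfig(
                image_height_px=384,
                image_width_px=384,
                debris_density_per_mm2=60.0,
                seed=seed,
            )
            truth, rgb = simulate_rgb(cfg)
            result = sliced_inference(rgb, detector, TilingConfig())
            match = match_detections(result.detections, truth.debris_boxes, 0.3)
            tp += len(match.pairs)
            n_det += len(result.detections)
            n_gt += len(truth.debris_boxes)
        assert n_gt >= 20
        assert tp / n_gt >= 0.6  # sensitivity
        assert tp / n_det >= 0.7  # precision

    def test_color_rotation_tta_makes_counts_invariant(self, trained_detector):
        # the augmentation's purpose: robustness to sample orientation.
        # With color-rotation TTA the detection count on a channel-rotated
        # image must match the original within 10%.
        detector, _ = trained_detector
        cfg = SectionSimConfig(
            image_height_px=256, image_width_px=256, debris_density_per_mm2=100.0, seed=31
        )
        _, rgb = simulate_rgb(cfg)
        kwargs = dict(
            tiling=TilingConfig(),
            tta=True,
            tta_geoms=("identity",),
            tta_colors=(0, 1, 2),
        )
        n_base = len(sliced_inference(rgb, detector, **kwargs).detections)
        n_rot = len(sliced_inference(color_rotate(rgb, 1), detector, **kwargs).detections)
        assert n_base > 0
        assert abs(n_rot - n_base) <= 0.1 * n_base
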