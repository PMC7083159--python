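"""Box extraction, IoU, matching, PR curves, AP/mAP, per-image IoU."""

import numpy as np
import pytest

from crmloc.exceptions import InputError
from crmloc.localization import (
    BoundingBox,
    Detection,
    GroundTruthRecord,
    PRCurve,
    average_precision,
    default_iou_thresholds,
    extract_boxes,
    iou,
    match_detections,
    mean_average_precision,
    mean_image_iou,
    pr_curve,
)
from crmloc.saliency import RelevanceMap


def det(image_id, x0, y0, x1, y1, conf):
    return Detection(image_id, BoundingBox(x0, y0, x1, y1), conf)


def random_box(rng, limit=50):
    x0, y0 = rng.integers(0, limit - 2, size=2)
    w, h = rng.integers(1, limit // 2, size=2)
    return BoundingBox(float(x0), float(y0), float(x0 + w), float(y0 + h))


def brute_force_ap(dets, gts, iou_threshold):
    """Independent AP oracle: re-match from scratch at every confidence cut."""
    confs = sorted({d.confidence for d in dets}, reverse=True)
    n_gt = sum(len(g.boxes) for g in gts)
    points = []
    for cut in confs:
        kept = [d for d in dets if d.confidence >= cut]
        labels, _ = match_detections(kept, gts, iou_threshold)
        tp = sum(labels)
        points.append((tp / len(kept), tp / n_gt))
    ap, prev = 0.0, 0.0
    for precision, recall in points:
        ap += (recall - prev) * precision
        prev = recall
    return ap


def random_instance(rng):
    gts = []
    for i in range(int(rng.integers(1, 4))):
        boxes = [random_box(rng) for _ in range(int(rng.integers(1, 6)))]
        gts.append(GroundTruthRecord(f"im{i}", tuple(boxes)))
    dets = []
    for _ in range(int(rng.integers(0, 11))):
        image_id = f"im{int(rng.integers(0, len(gts)))}"
        dets.append(Detection(image_id, random_box(rng), float(rng.random())))
    return dets, gts


class TestIou:
    def test_examples(self):
        a = BoundingBox(0, 0, 10, 10)
        assert iou(a, a) == 1.0
        assert iou(a, BoundingBox(20, 20, 30, 30)) == 0.0
        assert iou(a, BoundingBox(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_symmetry_range_identity_on_random_pairs(self, rng):
        for _ in range(1000):
            a, b = random_box(rng), random_box(rng)
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))
        assert iou(a, a) == 1.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(InputError):
            BoundingBox(5, 5, 5, 10)


class TestExtractBoxes:
    def test_zero_map_empty(self):
        assert extract_boxes(RelevanceMap(np.zeros((6, 6))), 0.9) == []

    def test_single_block_box_and_confidence(self):
        values = np.zeros((8, 10))
        values[2:5, 5:9] = 0.3
        values[3, 6] = 0.8  # in-box maximum
        dets = extract_boxes(RelevanceMap(values), classification_score=0.5)
        assert len(dets) == 1
        assert dets[0].box == BoundingBox(5, 2, 9, 5)
        assert dets[0].confidence == pytest.approx(0.4)

    def test_two_blocks_separated_by_zero_row(self):
        values = np.zeros((7, 4))
        values[0:2, :] = 1.0
        values[4:6, :] = 0.5
        assert len(extract_boxes(RelevanceMap(values), 1.0)) == 2

    def test_diagonal_touch_merges_with_8_connectivity(self):
        values = np.zeros((4, 4))
        values[0, 0] = values[1, 1] = 1.0
        assert len(extract_boxes(RelevanceMap(values), 1.0)) == 1

    @pytest.mark.parametrize("blocks", [1, 2, 3, 4, 5])
    def test_b_disjoint_blocks_give_b_detections(self, blocks):
        values = np.zeros((30, 30))
        for i in range(blocks):
            values[5 * i + i : 5 * i + i + 3, 2:6] = 1.0  # zero row between
        assert len(extract_boxes(RelevanceMap(values), 1.0)) == blocks

    def test_min_area_filter(self):
        values = np.zeros((10, 10))
        values[0, 0] = 1.0
        values[5:9, 5:9] = 1.0
        dets = extract_boxes(RelevanceMap(values), 1.0, min_area=4)
        assert len(dets) == 1 and dets[0].box.x_min == 5


class TestMatching:
    GT = [GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),))]

    def test_no_detections(self):
        labels, matched = match_detections([], self.GT, 0.5)
        assert labels == [] and matched["a"] == [False]

    def test_exact_match_is_tp(self):
        labels, matched = match_detections(
            [det("a", 0, 0, 10, 10, 0.9)], self.GT, 0.5
        )
        assert labels == [True] and matched["a"] == [True]

    def test_greedy_consumption_of_single_gt(self):
        dets = [det("a", 0, 0, 10, 10, 0.4), det("a", 1, 0, 11, 10, 0.9)]
        labels, _ = match_detections(dets, self.GT, 0.5)
        # processed in confidence order: the 0.9 detection wins the GT box
        assert labels == [True, False]

    def test_detection_for_unknown_image_is_fp(self):
        labels, _ = match_detections([det("zz", 0, 0, 5, 5, 1.0)], self.GT, 0.1)
        assert labels == [False]


class TestPrCurveAndAp:
    def test_single_perfect_detection(self):
        curve = pr_curve([det("a", 0, 0, 10, 10, 0.9)], TestMatching.GT, 0.5)
        assert curve.points == ((1.0, 1.0),)
        assert average_precision(curve) == 1.0

    def test_running_count_enumeration(self):
        gts = [GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),
                                       BoundingBox(20, 20, 30, 30)))]
        dets = [
            det("a", 0, 0, 10, 10, 0.9),     # TP
            det("a", 40, 40, 50, 50, 0.8),   # FP
            det("a", 20, 20, 30, 30, 0.7),   # TP
        ]
        curve = pr_curve(dets, gts, 0.5)
        assert curve.points == ((1.0, 0.5), (0.5, 0.5), (pytest.approx(2 / 3), 1.0))
        assert average_precision(curve) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_all_false_positives(self):
        dets = [det("a", 40, 40, 50, 50, c) for c in (0.9, 0.5)]
        curve = pr_curve(dets, TestMatching.GT, 0.5)
        assert all(p == 0.0 and r == 0.0 for p, r in curve.points)
        assert average_precision(curve) == 0.0

    def test_empty_detections_score_zero(self):
        assert average_precision(pr_curve([], TestMatching.GT, 0.5)) == 0.0

    def test_recall_non_decreasing_along_sweep(self, rng):
        for _ in range(50):
            dets, gts = random_instance(rng)
            if not dets:
                continue
            curve = pr_curve(dets, gts, 0.3)
            recalls = [r for _, r in curve.points]
            assert recalls == sorted(recalls)

    def test_zero_gt_boxes_rejected(self):
        with pytest.raises(InputError):
            pr_curve([], [GroundTruthRecord("a", ())], 0.5)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(100):
            dets, gts = random_instance(rng)
            for threshold in (0.1, 0.35, 0.6):
                fast = average_precision(pr_curve(dets, gts, threshold))
                assert fast == pytest.approx(
                    brute_force_ap(dets, gts, threshold), abs=1e-12
                )

    def test_ap_non_increasing_in_iou_threshold(self, rng):
        for _ in range(50):
            dets, gts = random_instance(rng)
            aps = [
                average_precision(pr_curve(dets, gts, t))
                for t in default_iou_thresholds()
            ]
            assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


class TestMap:
    def test_perfect_detections_score_one(self):
        gts = [GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),))]
        dets = [det("a", 0, 0, 10, 10, 0.9)]
        assert mean_average_precision(dets, gts) == 1.0

    def test_single_threshold_equals_ap(self, rng):
        dets, gts = random_instance(rng)
        assert mean_average_precision(dets, gts, [0.4]) == pytest.approx(
            average_precision(pr_curve(dets, gts, 0.4))
        )

    def test_decomposes_into_mean_of_per_threshold_aps(self, rng):
        dets, gts = random_instance(rng)
        thresholds = default_iou_thresholds()
        expected = np.mean(
            [average_precision(pr_curve(dets, gts, t)) for t in thresholds]
        )
        assert mean_average_precision(dets, gts) == pytest.approx(expected)

    def test_map_bracketed_by_extreme_thresholds(self, rng):
        for _ in range(20):
            dets, gts = random_instance(rng)
            lo = average_precision(pr_curve(dets, gts, 0.6))
            hi = average_precision(pr_curve(dets, gts, 0.1))
            m = mean_average_precision(dets, gts)
            assert lo - 1e-12 <= m <= hi + 1e-12

    def test_default_threshold_grid(self):
        grid = default_iou_thresholds()
        assert len(grid) == 10
        assert grid[0] == pytest.approx(0.1) and grid[-1] == pytest.approx(0.6)

    def test_empty_thresholds_rejected(self, rng):
        dets, gts = random_instance(rng)
        with pytest.raises(InputError):
            mean_average_precision(dets, gts, [])


class TestMeanImageIou:
    def test_exact_detections_score_one(self):
        gts = [
            GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),)),
            GroundTruthRecord("b", (BoundingBox(5, 5, 9, 9),)),
        ]
        dets = [det("a", 0, 0, 10, 10, 1.0), det("b", 5, 5, 9, 9, 1.0)]
        assert mean_image_iou(dets, gts) == 1.0

    def test_no_detections_score_zero(self):
        gts = [GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),))]
        assert mean_image_iou([], gts) == 0.0

    def test_one_of_two_gt_matched_scores_half(self):
        gts = [GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),
                                       BoundingBox(20, 20, 30, 30)))]
        dets = [det("a", 0, 0, 10, 10, 1.0)]
        assert mean_image_iou(dets, gts) == pytest.approx(0.5)

    def test_detection_used_at_most_once(self):
        gts = [GroundTruthRecord("a", (BoundingBox(0, 0, 10, 10),
                                       BoundingBox(0, 0, 12, 10)))]
        dets = [det("a", 0, 0, 10, 10, 1.0)]
        # the single detection pairs with its best GT (IoU 1), other GT gets 0
        assert mean_image_iou(dets, gts) == pytest.approx(0.5)

    def test_image_without_gt_boxes_rejected(self):
        with pytest.raises(InputError):
            mean_image_iou([], [GroundTruthRecord("a", ())])
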