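"""Tests for strict-IoU matching, per-class/image PQ and the two aggregations."""

import numpy as np
import pytest

from _oracles import brute_strict_match
from conftest import rect_scene, small_scene_pair
from iscmetrics.exceptions import ConfigurationError, UndefinedMetricError
from iscmetrics.panoptic import (
    MatchResult,
    aggregate_pq,
    match_all_classes,
    match_by_iou,
    pq_class_image,
    pq_table,
)
from iscmetrics.scene import AnnotatedScene


class TestStrictMatching:
    def test_low_iou_prediction_unmatched(self):
        """A prediction at IoU 0.2 counts as one FP and one FN."""
        gt = rect_scene((20, 20), [(1, 0, 0, 10, 10)], {1: 1})
        pred = rect_scene((20, 20), [(1, 0, 0, 2, 10)], {1: 1})  # IoU = 20/100
        m = match_by_iou(gt, pred, class_label=1)
        assert m.pairs == []
        assert m.unmatched_gt == [1]
        assert m.unmatched_pred == [1]

    def test_identical_scenes_fully_matched(self):
        gt = rect_scene((30, 30), [(1, 0, 0, 5, 5), (2, 10, 10, 6, 6)], {1: 1, 2: 1})
        m = match_by_iou(gt, gt, class_label=1)
        assert [(g, p) for g, p, _ in m.pairs] == [(1, 1), (2, 2)]
        assert all(i == 1.0 for _, _, i in m.pairs)
        assert m.unmatched_gt == m.unmatched_pred == []

    def test_iou_exactly_half_is_unmatched(self):
        gt = rect_scene((20, 20), [(1, 0, 0, 10, 10)], {1: 1})
        pred = rect_scene((20, 20), [(1, 0, 0, 5, 10)], {1: 1})  # IoU exactly 0.5
        m = match_by_iou(gt, pred, class_label=1)
        assert m.pairs == []

    def test_threshold_below_half_rejected(self):
        gt = rect_scene((10, 10), [(1, 0, 0, 2, 2)], {1: 1})
        with pytest.raises(ConfigurationError):
            match_by_iou(gt, gt, class_label=1, threshold=0.3)

    def test_classes_never_cross_match(self):
        gt = rect_scene((20, 20), [(1, 0, 0, 10, 10)], {1: 1})
        pred = rect_scene((20, 20), [(1, 0, 0, 10, 10)], {1: 2})
        results = match_all_classes(gt, pred)
        assert results[1].pairs == [] and results[1].unmatched_gt == [1]
        assert results[2].unmatched_pred == [1]

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_on_random_scenes(self, seed):
        gt, pred = small_scene_pair(seed)
        results = match_all_classes(gt, pred)
        for c, m in results.items():
            gt_masks = {i: gt.mask(i) for i in gt.instance_ids() if gt.class_of[i] == c}
            pred_masks = {i: pred.mask(i) for i in pred.instance_ids()
                          if pred.class_of[i] == c}
            expected = brute_strict_match(gt_masks, pred_masks)
            got = sorted((g, p, i) for g, p, i in m.pairs)
            assert [(g, p) for g, p, _ in got] == [(g, p) for g, p, _ in expected]
            for (_, _, a), (_, _, b) in zip(got, expected):
                assert a == pytest.approx(b)

    def test_ambiguous_region_excluded_before_matching(self):
        """Pixels under the ambiguous mask do not count; emptied instances vanish."""
        amb = np.zeros((20, 20), bool)
        amb[0:10, 0:10] = True
        gt = AnnotatedScene(
            rect_scene((20, 20), [(1, 0, 0, 10, 10), (2, 12, 12, 5, 5)], {1: 1, 2: 1}).instance_map,
            {1: 1, 2: 1}, ambiguous_mask=amb)
        pred = rect_scene((20, 20), [(7, 12, 12, 5, 5)], {7: 1})
        m = match_by_iou(gt, pred, class_label=1)
        # instance 1 was fully ambiguous: neither matched nor a false negative
        assert [(g, p) for g, p, _ in m.pairs] == [(2, 7)]
        assert m.unmatched_gt == []


class TestClassImagePQ:
    def test_hand_computed_example(self):
        m = MatchResult(1, pairs=[(1, 1, 0.8), (2, 2, 0.9)], unmatched_pred=[3])
        r = pq_class_image(m)
        assert r.rq == pytest.approx(0.8)
        assert r.sq == pytest.approx(0.85)
        assert r.pq == pytest.approx(0.68)

    def test_perfect_prediction(self):
        m = MatchResult(1, pairs=[(i, i, 1.0) for i in range(5)])
        r = pq_class_image(m)
        assert (r.rq, r.sq, r.pq) == (1.0, 1.0, 1.0)

    def test_no_predictions_sq_undefined(self):
        m = MatchResult(1, unmatched_gt=[1, 2])
        r = pq_class_image(m)
        assert r.pq == 0.0 and r.rq == 0.0 and r.sq is None

    def test_nothing_at_all_everything_undefined(self):
        r = pq_class_image(MatchResult(1))
        assert r.rq is None and r.sq is None and r.pq is None

    @pytest.mark.parametrize("seed", range(4))
    def test_decomposition_pq_equals_rq_times_sq(self, seed):
        gt, pred = small_scene_pair(seed + 50)
        for m in match_all_classes(gt, pred).values():
            r = pq_class_image(m)
            if r.tp > 0:
                assert r.pq == pytest.approx(r.rq * r.sq, abs=1e-12)


def fig_style_toy_dataset():
    """Three images with nested-rectangle instances of exactly known IoUs.

    Image 0: blue (1) gts matched at IoU 0.9 and 0.8; orange (2) gt at 0.7.
    Image 1: blue gt with a 0.2-IoU prediction (unmatched) and an orange gt
    predicted with high overlap but the wrong (blue) class.
    Image 2: blue gt matched at 0.6; no orange anywhere.
    """
    shape = (60, 60)
    gt0 = rect_scene(shape, [(1, 0, 0, 10, 10), (2, 20, 0, 10, 10), (3, 40, 0, 10, 10)],
                     {1: 1, 2: 1, 3: 2})
    pr0 = rect_scene(shape, [(1, 0, 0, 9, 10), (2, 20, 0, 8, 10), (3, 40, 0, 7, 10)],
                     {1: 1, 2: 1, 3: 2})
    gt1 = rect_scene(shape, [(1, 0, 0, 10, 10), (2, 20, 0, 10, 10)], {1: 1, 2: 2})
    pr1 = rect_scene(shape, [(1, 0, 0, 2, 10), (2, 20, 0, 9, 10)], {1: 1, 2: 1})
    gt2 = rect_scene(shape, [(1, 0, 0, 10, 10)], {1: 1})
    pr2 = rect_scene(shape, [(1, 0, 0, 6, 10)], {1: 1})
    return [gt0, gt1, gt2], [pr0, pr1, pr2]


class TestAggregations:
    def test_perfect_prediction_gives_one(self):
        gt = rect_scene((30, 30), [(1, 0, 0, 5, 5), (2, 10, 10, 6, 6)], {1: 1, 2: 2})
        agg = aggregate_pq([gt], [gt])
        assert agg.apq == 1.0 and agg.mpq == 1.0

    def test_apq_equals_mpq_on_single_image_with_all_classes(self):
        gt, pred = small_scene_pair(3)
        agg = aggregate_pq([gt], [pred])
        if set(gt.classes_present()) | set(pred.classes_present()) == set(agg.classes):
            assert agg.apq == pytest.approx(agg.mpq)

    def test_toy_dataset_hand_computation(self):
        """aPQ and mPQ evaluated by hand from the toy dataset's known IoUs."""
        gts, preds = fig_style_toy_dataset()
        agg = aggregate_pq(gts, preds)
        # image 0: blue (0.9+0.8)/2, orange 0.7 -> PQ_0 = (0.85+0.7)/2
        # image 1: blue tp=0,fp=2,fn=1 -> 0; orange fn=1 -> 0 -> PQ_1 = 0
        # image 2: only blue, 0.6
        apq_hand = ((0.85 + 0.7) / 2 + 0.0 + 0.6) / 3
        # pooled blue: iou_sum 2.3, tp=3, fp=2, fn=1 -> 2.3/4.5
        # pooled orange: iou_sum 0.7, tp=1, fn=1 -> 0.7/1.5
        mpq_hand = (2.3 / 4.5 + 0.7 / 1.5) / 2
        assert agg.apq == pytest.approx(apq_hand)
        assert agg.mpq == pytest.approx(mpq_hand)

    def test_constant_iou_class_pools_to_sq(self):
        """All detections correct at IoU 0.6 -> pooled class PQ equals 0.6."""
        shape = (40, 40)
        gts = [rect_scene(shape, [(1, 0, 0, 10, 10), (2, 20, 0, 10, 10)], {1: 1, 2: 1})]
        preds = [rect_scene(shape, [(1, 0, 0, 6, 10), (2, 20, 0, 6, 10)], {1: 1, 2: 1})]
        agg = aggregate_pq(gts, preds)
        assert agg.per_class_pooled[1] == pytest.approx(0.6)

    def test_pooled_counts_equal_sum_of_per_image_counts(self):
        pairs = [small_scene_pair(s) for s in (11, 12, 13, 14, 15)]
        gts = [g for g, _ in pairs]
        preds = [p for _, p in pairs]
        table = pq_table(gts, preds)
        agg = aggregate_pq(gts, preds)
        for c in agg.classes:
            rows = table[table["class_label"] == c]
            pooled_denominator = rows.tp.sum() + 0.5 * rows.fp.sum() + 0.5 * rows.fn.sum()
            if pooled_denominator > 0:
                iou_sum = sum(
                    m.iou_sum for g, p in zip(gts, preds)
                    for cl, m in match_all_classes(g, p).items() if cl == c
                )
                assert agg.per_class_pooled[c] == pytest.approx(iou_sum / pooled_denominator)

    def test_misclassified_detection_worse_than_missed(self):
        """Perfect-overlap wrong-class detection scores below a plain miss."""
        shape = (40, 40)
        gt = rect_scene(shape, [(1, 0, 0, 8, 8), (2, 10, 10, 8, 8), (3, 20, 20, 8, 8)],
                        {1: 1, 2: 2, 3: 1})
        wrong = rect_scene(shape, [(1, 0, 0, 8, 8), (2, 10, 10, 8, 8), (3, 20, 20, 8, 8)],
                           {1: 1, 2: 2, 3: 2})  # instance 3 misclassified
        missed = rect_scene(shape, [(1, 0, 0, 8, 8), (2, 10, 10, 8, 8)], {1: 1, 2: 2})
        agg_wrong = aggregate_pq([gt], [wrong])
        agg_missed = aggregate_pq([gt], [missed])
        assert agg_wrong.apq < agg_missed.apq
        assert agg_wrong.mpq < agg_missed.mpq

    def test_false_positive_never_helps(self):
        gt, pred = small_scene_pair(21)
        with_fp = pred.instance_map.copy()
        free = np.argwhere(with_fp == 0)
        r, c = free[0]
        with_fp[r:r + 3, c:c + 3][with_fp[r:r + 3, c:c + 3] == 0] = 9999
        class_of = dict(pred.class_of)
        class_of[9999] = gt.classes_present()[0]
        pred_fp = AnnotatedScene(with_fp, class_of)
        base = aggregate_pq([gt], [pred])
        worse = aggregate_pq([gt], [pred_fp])
        assert worse.apq <= base.apq
        assert worse.mpq <= base.mpq

    def test_empty_dataset_is_error(self):
        with pytest.raises(UndefinedMetricError):
            aggregate_pq([], [])
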