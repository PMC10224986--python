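"""Tests for the alternative matchers, the ISC confusion matrix and the
separated detection/classification metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import rect_scene, small_scene_pair
from iscmetrics.exceptions import ConfigurationError, UndefinedMetricError
from iscmetrics.matching import (
    ConfusionISC,
    balanced_accuracy,
    confusion_isc,
    detection_f1,
    match_by_centroid,
    match_by_overlap,
    sum_of_ranks,
)
from iscmetrics.scene import AnnotatedScene
from iscmetrics.synthetic import DegradationSpec, degrade


class TestOverlapMatching:
    def test_largest_iou_wins(self):
        gt = rect_scene((20, 20), [(1, 0, 0, 10, 10)], {1: 1})
        # pred 1 overlaps 30 px (IoU 30/170), pred 2 overlaps 60 px (IoU 60/100)
        pred = rect_scene((20, 20), [(1, 0, 0, 3, 10), (2, 3, 0, 6, 10)], {1: 1, 2: 1})
        m = match_by_overlap(gt, pred)
        assert [(g, p) for g, p, _ in m.pairs] == [(1, 2)]
        assert m.unmatched_pred == [1]

    def test_disjoint_scenes_no_pairs(self):
        gt = rect_scene((20, 20), [(1, 0, 0, 4, 4)], {1: 1})
        pred = rect_scene((20, 20), [(1, 10, 10, 4, 4)], {1: 1})
        m = match_by_overlap(gt, pred)
        assert m.pairs == []
        assert m.unmatched_gt == [1] and m.unmatched_pred == [1]

    def test_matches_class_agnostically(self):
        gt = rect_scene((20, 20), [(1, 0, 0, 8, 8)], {1: 1})
        pred = rect_scene((20, 20), [(5, 0, 0, 8, 8)], {5: 2})
        m = match_by_overlap(gt, pred)
        assert [(g, p) for g, p, _ in m.pairs] == [(1, 5)]

    @pytest.mark.parametrize("seed", range(5))
    def test_one_to_one_and_greedy_optimal(self, seed):
        """Each object appears once; every pair beats any discarded conflict."""
        gt, pred = small_scene_pair(seed + 30)
        m = match_by_overlap(gt, pred)
        gs = [g for g, _, _ in m.pairs]
        ps = [p for _, p, _ in m.pairs]
        assert len(gs) == len(set(gs)) and len(ps) == len(set(ps))
        # greedy by descending IoU: recompute by brute force
        from iscmetrics.scene import instance_areas, overlap_table
        areas_g = instance_areas(gt.instance_map)
        areas_p = instance_areas(pred.instance_map)
        table = overlap_table(gt.instance_map, pred.instance_map)
        cands = sorted(
            ((-(i / (areas_g[g] + areas_p[p] - i)), g, p) for (g, p), i in table.items())
        )
        used_g, used_p, expected = set(), set(), []
        for negiou, g, p in cands:
            if g not in used_g and p not in used_p:
                used_g.add(g)
                used_p.add(p)
                expected.append((g, p))
        assert sorted((g, p) for g, p, _ in m.pairs) == sorted(expected)


class TestCentroidMatching:
    def test_greedy_by_closeness(self):
        """Distance matrix [[1,4],[3,2]] assigns (g1,p1) then (g2,p2)."""
        shape = (40, 40)
        gt = rect_scene(shape, [(1, 10, 10, 1, 1), (2, 10, 13, 1, 1)], {1: 1, 2: 1})
        pred = rect_scene(shape, [(1, 11, 10, 1, 1), (2, 10, 15, 1, 1)], {1: 1, 2: 1})
        # d(g1,p1)=1, d(g1,p2)=5, d(g2,p1)=sqrt(10), d(g2,p2)=2
        m = match_by_centroid(gt, pred, radius=10)
        assert sorted((g, p) for g, p, _ in m.pairs) == [(1, 1), (2, 2)]

    def test_beyond_radius_unmatched(self):
        gt = rect_scene((40, 40), [(1, 0, 0, 2, 2)], {1: 1})
        pred = rect_scene((40, 40), [(1, 30, 30, 2, 2)], {1: 1})
        m = match_by_centroid(gt, pred, radius=5)
        assert m.pairs == []

    def test_identical_scenes_distance_zero(self):
        gt, _ = small_scene_pair(77)
        m = match_by_centroid(gt, gt, radius=5)
        assert sorted((g, p) for g, p, _ in m.pairs) == [(i, i) for i in gt.instance_ids()]
        assert all(i == 1.0 for _, _, i in m.pairs)

    def test_radius_must_be_positive(self):
        gt, _ = small_scene_pair(78)
        with pytest.raises(ConfigurationError):
            match_by_centroid(gt, gt, radius=0)


class TestConfusionISC:
    def test_perfect_prediction_is_diagonal(self):
        gt = rect_scene((40, 40), [(1, 0, 0, 5, 5), (2, 10, 10, 5, 5), (3, 20, 20, 5, 5)],
                        {1: 1, 2: 2, 3: 3})
        conf = confusion_isc(gt, gt, match_by_overlap(gt, gt))
        assert (np.diag(conf.counts)[1:] == 1).all()
        assert conf.counts.sum() == 3
        assert conf.counts[0, 0] == 0

    def test_misclassified_detection_lands_off_diagonal(self):
        """A macrophage predicted as epithelial is one count at (macro, epi)."""
        gt = rect_scene((20, 20), [(1, 0, 0, 8, 8)], {1: 4})
        pred = rect_scene((20, 20), [(1, 0, 0, 8, 8)], {1: 1})
        conf = confusion_isc(gt, pred, match_by_overlap(gt, pred), classes=[1, 4])
        # classes [1, 4] -> rows/cols [bg, 1, 4]
        assert conf.counts[2, 1] == 1
        assert conf.counts.sum() == 1

    def test_row_sums_fixed_by_ground_truth(self):
        """Rows 1..m are identical across two different synthetic predictors."""
        gt, _ = small_scene_pair(41, n_instances=10)
        pred_a, _ = degrade(gt, DegradationSpec(dropout_rate=0.3), seed=1)
        pred_b, _ = degrade(gt, DegradationSpec(misclassification_rate=0.5,
                                                spurious_rate=2.0), seed=2)
        classes = gt.classes_present()
        conf_a = confusion_isc(gt, pred_a, match_by_overlap(gt, pred_a), classes=classes)
        conf_b = confusion_isc(gt, pred_b, match_by_overlap(gt, pred_b), classes=classes)
        assert (conf_a.counts[1:, :].sum(axis=1) == conf_b.counts[1:, :].sum(axis=1)).all()
        # total sum differs in general: row 0 depends on the predictor alone
        gt_counts = np.array([sum(1 for i in gt.instance_ids() if gt.class_of[i] == c)
                              for c in classes])
        assert (conf_a.counts[1:, :].sum(axis=1) == gt_counts).all()


class TestSeparatedMetrics:
    def test_detection_f1_hand_example(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[1, 1] = 2  # 2 matched
        counts[0, 1] = 1  # 1 spurious prediction
        counts[2, 0] = 1  # 1 missed gt
        conf = ConfusionISC(classes=[1, 2], counts=counts)
        assert detection_f1(conf) == pytest.approx(4 / 6)

    def test_detection_f1_perfect_and_zero(self):
        perfect = ConfusionISC([1], np.array([[0, 0], [0, 3]]))
        assert detection_f1(perfect) == 1.0
        nothing = ConfusionISC([1], np.array([[0, 0], [4, 0]]))
        assert detection_f1(nothing) == 0.0

    def test_detection_f1_invariant_to_class_permutation(self):
        gt, pred = small_scene_pair(55)
        m = match_by_overlap(gt, pred)
        conf = confusion_isc(gt, pred, m)
        swap = {1: 2, 2: 1}
        gt2 = AnnotatedScene(gt.instance_map, {k: swap[v] for k, v in gt.class_of.items()})
        pred2 = AnnotatedScene(pred.instance_map,
                               {k: swap[v] for k, v in pred.class_of.items()})
        conf2 = confusion_isc(gt2, pred2, match_by_overlap(gt2, pred2))
        assert detection_f1(conf) == pytest.approx(detection_f1(conf2))

    def test_balanced_accuracy_hand_example(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[1:, 1:] = [[3, 1], [2, 2]]
        conf = ConfusionISC(classes=[1, 2], counts=counts)
        assert balanced_accuracy(conf) == pytest.approx(0.625)

    def test_balanced_accuracy_diagonal_is_one(self):
        conf = ConfusionISC([1, 2], np.diag([0, 5, 7]))
        assert balanced_accuracy(conf) == 1.0

    def test_balanced_accuracy_all_misclassified_class(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[1:, 1:] = [[4, 0], [3, 0]]  # class 2 never correct
        conf = ConfusionISC(classes=[1, 2], counts=counts)
        assert balanced_accuracy(conf) == pytest.approx(0.5)

    def test_balanced_accuracy_undefined_without_matches(self):
        conf = ConfusionISC([1], np.array([[0, 2], [3, 0]]))
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(conf)


class TestSumOfRanks:
    def test_dominating_method(self):
        scores = pd.DataFrame({"f1": [0.9, 0.5], "hd": [1.0, 3.0]}, index=["a", "b"])
        table = sum_of_ranks(scores, {"f1": True, "hd": False})
        assert table.rank_sums["a"] == 2.0
        assert table.rank_sums["b"] == 4.0

    def test_symmetric_split(self):
        scores = pd.DataFrame({"f1": [0.9, 0.5], "acc": [0.4, 0.8]}, index=["a", "b"])
        table = sum_of_ranks(scores, {"f1": True, "acc": True})
        assert table.rank_sums["a"] == table.rank_sums["b"]

    def test_three_by_three_hand_ranked(self):
        scores = pd.DataFrame(
            {"m1": [0.3, 0.2, 0.1], "m2": [5.0, 5.0, 1.0], "m3": [0.5, 0.9, 0.7]},
            index=["a", "b", "c"],
        )
        table = sum_of_ranks(scores, {"m1": True, "m2": False, "m3": True})
        # m1: a=1 b=2 c=3; m2 (lower better): c=1, a=b=2.5 midrank; m3: b=1 c=2 a=3
        assert table.ranks.loc["a"].tolist() == [1.0, 2.5, 3.0]
        assert table.rank_sums.tolist() == [6.5, 5.5, 6.0]

    def test_missing_score_rejected(self):
        scores = pd.DataFrame({"m": [0.1, float("nan")]}, index=["a", "b"])
        with pytest.raises(ConfigurationError):
            sum_of_ranks(scores, {"m": True})
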