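"""Alternative matching rules and separated detection/classification metrics.

The strict ``IoU > 0.5`` rule rejects many detections that a pathologist
would accept, especially on small nuclei whose boundary fuzziness alone
pushes IoU below the threshold.  This module provides two class-agnostic
alternatives — any-overlap matching with a largest-IoU tie-break, and
greedy minimal-centroid-distance matching within a tolerance radius — plus
the object-level confusion matrix with an explicit background row/column,
and the separated metrics built on it: detection F1 on a single
"nucleus vs background" class, balanced accuracy on the classes of the
matched nuclei, and a sum-of-ranks aggregation for comparing methods
across several metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, UndefinedMetricError
from .panoptic import MatchResult, _prepare
from .scene import AnnotatedScene, instance_areas, overlap_table

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionISC",
    "RankTable",
    "match_by_overlap",
    "match_by_centroid",
    "confusion_isc",
    "detection_f1",
    "balanced_accuracy",
    "sum_of_ranks",
    "DEFAULT_CENTROID_RADIUS",
]

#: Default centroid-matching tolerance radius in pixels at 0.25 µm/px
#: (roughly one typical nucleus radius).
DEFAULT_CENTROID_RADIUS = 15.0


def _greedy_one_to_one(
    candidates: list[tuple[float, int, int, float]],
    gt_ids: Sequence[int],
    pred_ids: Sequence[int],
) -> MatchResult:
    """Assign candidates (sort_key, gt, pred, iou) greedily, one-to-one.

    Candidates must already be sorted; ties are broken by (gt ID, pred ID)
    lexicographic order upstream, which makes the result order-independent.
    """
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for _, g, p, iou_val in candidates:
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        pairs.append((g, p, iou_val))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return MatchResult(
        class_label=None,
        pairs=pairs,
        unmatched_gt=sorted(set(gt_ids) - used_g),
        unmatched_pred=sorted(set(pred_ids) - used_p),
    )


def match_by_overlap(gt: AnnotatedScene, pred: AnnotatedScene) -> MatchResult:
    """Any-overlap matching, class-agnostic: the loosest possible match rule.

    Every overlapping (gt, pred) pair is a candidate; when an object has
    several candidates the one with the largest IoU wins, and remaining
    conflicts are resolved greedily in descending IoU order.  The result is
    one-to-one.
    """
    gt, pred = _prepare(gt, pred)
    gt_areas = instance_areas(gt.instance_map)
    pred_areas = instance_areas(pred.instance_map)
    table = overlap_table(gt.instance_map, pred.instance_map)
    candidates = []
    for (g, p), inter in table.items():
        iou_val = inter / (gt_areas[g] + pred_areas[p] - inter)
        candidates.append((-iou_val, g, p, iou_val))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    return _greedy_one_to_one(candidates, list(gt_areas), list(pred_areas))


def match_by_centroid(
    gt: AnnotatedScene,
    pred: AnnotatedScene,
    radius: float = DEFAULT_CENTROID_RADIUS,
) -> MatchResult:
    """Greedy minimal-centroid-distance matching within a tolerance radius.

    All (gt, pred) pairs whose centroid distance is at most ``radius`` are
    sorted by distance (ties broken by IDs) and assigned in order of
    closeness; once an object is assigned, its other candidate pairs are
    discarded.  The IoU stored with each pair is the actual pixel IoU
    (0.0 for disjoint-but-close pairs).
    """
    if radius <= 0:
        raise ConfigurationError(f"radius must be positive, got {radius}")
    gt, pred = _prepare(gt, pred)
    gt_areas = instance_areas(gt.instance_map)
    pred_areas = instance_areas(pred.instance_map)
    gt_ids = sorted(gt_areas)
    pred_ids = sorted(pred_areas)
    if not gt_ids or not pred_ids:
        return MatchResult(None, [], unmatched_gt=gt_ids, unmatched_pred=pred_ids)
    gt_cent = np.array(ndimage.center_of_mass(
        np.ones(gt.shape), gt.instance_map, gt_ids))
    pred_cent = np.array(ndimage.center_of_mass(
        np.ones(pred.shape), pred.instance_map, pred_ids))
    dists = cdist(gt_cent, pred_cent)
    table = overlap_table(gt.instance_map, pred.instance_map)
    candidates = []
    for i, j in np.argwhere(dists <= radius):
        g, p = gt_ids[i], pred_ids[j]
        inter = table.get((g, p), 0)
        iou_val = inter / (gt_areas[g] + pred_areas[p] - inter) if inter else 0.0
        candidates.append((float(dists[i, j]), g, p, iou_val))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    return _greedy_one_to_one(candidates, gt_ids, pred_ids)


@dataclass
class ConfusionISC:
    """Object-level (m+1)x(m+1) confusion matrix with a background row/column.

    Row = ground-truth class, column = predicted class, index 0 =
    background.  Cell (0, 0) is fixed at 0 and not countable: there are no
    "correctly predicted background objects".  The first row holds false
    detections (predicted objects with no ground-truth match), the first
    column missed detections.  Because each ground-truth object of class
    ``a`` lands somewhere in row ``a``, the sums of rows 1..m are fixed by
    the ground truth regardless of the prediction; the total matrix sum is
    not, since row 0 depends only on the predictor's false detections.
    """

    classes: list[int]
    counts: np.ndarray

    @property
    def m(self) -> int:
        return len(self.classes)

    def matched_submatrix(self) -> np.ndarray:
        """The m x m classification-only block (rows/cols 1..m)."""
        return self.counts[1:, 1:]

    def to_frame(self) -> pd.DataFrame:
        labels = ["background"] + [str(c) for c in self.classes]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def confusion_isc(
    gt: AnnotatedScene,
    pred: AnnotatedScene,
    match: MatchResult,
    classes: Sequence[int] | None = None,
) -> ConfusionISC:
    """Build the detection confusion matrix from a class-agnostic matching.

    A matched pair with ground-truth class ``a`` and predicted class ``b``
    increments cell (a, b); an unmatched ground truth of class ``a``
    increments (a, 0); an unmatched prediction of class ``b`` increments
    (0, b).
    """
    if classes is None:
        classes = sorted(set(gt.classes_present()) | set(pred.classes_present()))
    classes = list(classes)
    index = {c: i + 1 for i, c in enumerate(classes)}
    counts = np.zeros((len(classes) + 1, len(classes) + 1), dtype=np.int64)
    for g, p, _ in match.pairs:
        counts[index[gt.class_of[g]], index[pred.class_of[p]]] += 1
    for g in match.unmatched_gt:
        counts[index[gt.class_of[g]], 0] += 1
    for p in match.unmatched_pred:
        counts[0, index[pred.class_of[p]]] += 1
    return ConfusionISC(classes=classes, counts=counts)


def detection_f1(conf: ConfusionISC) -> float:
    """Detection F1 on a single "nucleus vs background" class.

    All target classes collapse into one foreground class: every matched
    object is a detection TP whatever its classes, row 0 holds the FPs and
    column 0 the FNs.
    """
    tp = int(conf.counts[1:, 1:].sum())
    fp = int(conf.counts[0, :].sum())
    fn = int(conf.counts[:, 0].sum())
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise UndefinedMetricError("detection F1 undefined: no objects at all")
    return 2 * tp / denom


def balanced_accuracy(conf: ConfusionISC) -> float:
    """Mean per-class recall over the matched-objects submatrix.

    Classification quality of the detected nuclei only: missed and spurious
    detections are deliberately excluded (they belong to the detection
    metric).  Classes with no matched ground-truth object are excluded from
    the mean with a warning.
    """
    sub = conf.matched_submatrix()
    row_sums = sub.sum(axis=1)
    if not row_sums.any():
        raise UndefinedMetricError("balanced accuracy undefined: no matched objects")
    recalls = []
    for i, c in enumerate(conf.classes):
        if row_sums[i] == 0:
            logger.warning("class %s has no matched objects; excluded from balanced accuracy", c)
            continue
        recalls.append(sub[i, i] / row_sums[i])
    return float(np.mean(recalls))


@dataclass
class RankTable:
    """Per-metric ranks and their per-method sums for a method comparison.

    ``ranks`` assigns rank 1 to the best method on each metric (respecting
    the metric's orientation), with mid-ranks on ties; a lower ``rank_sums``
    entry means a better overall standing.
    """

    scores: pd.DataFrame
    ranks: pd.DataFrame
    rank_sums: pd.Series


def sum_of_ranks(
    scores: pd.DataFrame,
    higher_is_better: Mapping[str, bool] | Sequence[bool],
) -> RankTable:
    """Rank methods per metric and sum the ranks (rows = methods, cols = metrics)."""
    if scores.shape[0] < 2:
        raise ConfigurationError("sum of ranks needs at least two methods")
    if scores.shape[1] < 1:
        raise ConfigurationError("sum of ranks needs at least one metric")
    if scores.isna().any().any():
        raise ConfigurationError("missing scores are not imputed; fill them first")
    if not isinstance(higher_is_better, Mapping):
        if len(higher_is_better) != scores.shape[1]:
            raise ConfigurationError("one orientation flag per metric is required")
        higher_is_better = dict(zip(scores.columns, higher_is_better))
    ranks = pd.DataFrame(index=scores.index, dtype=float)
    for col in scores.columns:
        ranks[col] = scores[col].rank(ascending=not higher_is_better[col], method="average")
    return RankTable(scores=scores, ranks=ranks, rank_sums=ranks.sum(axis=1))
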