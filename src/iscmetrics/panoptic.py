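"""Panoptic Quality: strict IoU matching, per-class/image PQ, and both aggregations.

For each class ``c`` the ground-truth instances ``G_c = {g_k}`` and
predicted instances ``P_c = {p_l}`` are matched by the strict rule
``IoU(g_k, p_l) > 0.5``; strictness at the threshold means a pair at
exactly 0.5 stays unmatched.  Above 0.5 the match is automatically unique
(two predictions cannot each cover more than half of the same object), so
the matched pairs, unmatched predictions and unmatched ground truths form
the object-level TP/FP/FN sets, from which

.. math::

    RQ = \\frac{|TP|}{|TP| + \\tfrac12|FP| + \\tfrac12|FN|}, \\qquad
    SQ = \\frac{\\sum_{TP} IoU}{|TP|}, \\qquad
    PQ = SQ \\times RQ .

Two published aggregation schemes are provided: ``aPQ`` averages a
per-image mean of per-class PQ values over images, and ``mPQ`` pools the
TP/FP/FN counts and IoU sums per class over the whole dataset before
averaging over classes.

Undefined quantities (e.g. SQ when there are no true positives) are
represented as ``None``, never silently as 0; every coercion to 0 during
aggregation is logged.  Missing-class policy: a class present in exactly
one of ground truth or prediction of an image contributes PQ = 0 to that
image; a class absent from both is excluded from the image's class count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UndefinedMetricError
from .scene import AnnotatedScene, instance_areas, overlap_table

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "ClassImagePQ",
    "AggregatePQ",
    "match_by_iou",
    "match_all_classes",
    "pq_class_image",
    "aggregate_pq",
    "apq",
    "mpq",
    "pq_table",
]


@dataclass
class MatchResult:
    """One-to-one matching between ground-truth and predicted instances.

    ``pairs`` holds ``(gt_id, pred_id, iou)`` triples; every ID appears in
    at most one pair.  ``class_label`` is ``None`` for class-agnostic
    matchings (see :mod:`iscmetrics.matching`).
    """

    class_label: int | None
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_gt: list[int] = field(default_factory=list)
    unmatched_pred: list[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    @property
    def iou_sum(self) -> float:
        return float(sum(i for _, _, i in self.pairs))


@dataclass
class ClassImagePQ:
    """TP/FP/FN counts, IoU sum and the RQ/SQ/PQ values for one (class, image).

    ``rq``, ``sq`` and ``pq`` are ``None`` where undefined: all three when
    the class is absent from both ground truth and prediction; ``sq`` alone
    when there are detections or misses but no true positive.
    """

    tp: int
    fp: int
    fn: int
    iou_sum: float
    rq: float | None
    sq: float | None
    pq: float | None


@dataclass
class AggregatePQ:
    """Dataset-level PQ under both aggregation schemes.

    ``apq`` is the mean over images of the per-image mean of per-class PQ;
    ``mpq`` is the mean over classes of the dataset-pooled per-class PQ.
    """

    apq: float
    mpq: float
    per_image: list[float]
    per_class_pooled: dict[int, float]
    n_images: int
    classes: list[int]
    per_image_class_counts: list[int]


def _prepare(gt: AnnotatedScene, pred: AnnotatedScene) -> tuple[AnnotatedScene, AnnotatedScene]:
    """Apply the union of both scenes' ambiguous masks to both scenes."""
    if gt.shape != pred.shape:
        raise ConfigurationError(f"scene shapes differ: {gt.shape} vs {pred.shape}")
    extra_for_gt = pred.ambiguous_mask
    extra_for_pred = gt.ambiguous_mask
    return gt.without_ambiguous(extra_for_gt), pred.without_ambiguous(extra_for_pred)


def match_all_classes(
    gt: AnnotatedScene, pred: AnnotatedScene, threshold: float = 0.5
) -> dict[int, MatchResult]:
    """Strict-IoU matching for every class present in either scene.

    Ambiguous-region pixels (union of both scenes' masks) are removed from
    all instances before any overlap computation; instances emptied by the
    removal are dropped entirely.
    """
    if threshold < 0.5:
        raise ConfigurationError(
            f"IoU threshold must be >= 0.5 to guarantee unique matches, got {threshold}"
        )
    gt, pred = _prepare(gt, pred)
    gt_areas = instance_areas(gt.instance_map)
    pred_areas = instance_areas(pred.instance_map)
    table = overlap_table(gt.instance_map, pred.instance_map)

    classes = sorted(set(gt.classes_present()) | set(pred.classes_present()))
    results: dict[int, MatchResult] = {}
    for c in classes:
        gt_ids = [i for i in gt_areas if gt.class_of[i] == c]
        pred_ids = [i for i in pred_areas if pred.class_of[i] == c]
        pairs = []
        for (g, p), inter in table.items():
            if gt.class_of.get(g) != c or pred.class_of.get(p) != c:
                continue
            val = inter / (gt_areas[g] + pred_areas[p] - inter)
            if val > threshold:
                pairs.append((g, p, val))
        pairs.sort(key=lambda t: (t[0], t[1]))
        matched_g = {g for g, _, _ in pairs}
        matched_p = {p for _, p, _ in pairs}
        if len(matched_g) != len(pairs) or len(matched_p) != len(pairs):
            # unreachable for threshold >= 0.5; guards the uniqueness argument
            raise AssertionError("non-unique match above the 0.5 threshold")
        results[c] = MatchResult(
            class_label=c,
            pairs=pairs,
            unmatched_gt=sorted(set(gt_ids) - matched_g),
            unmatched_pred=sorted(set(pred_ids) - matched_p),
        )
    return results


def match_by_iou(
    gt: AnnotatedScene,
    pred: AnnotatedScene,
    class_label: int,
    threshold: float = 0.5,
) -> MatchResult:
    """Strict-IoU matching (``IoU > threshold``) for one class."""
    results = match_all_classes(gt, pred, threshold=threshold)
    if class_label in results:
        return results[class_label]
    return MatchResult(class_label=class_label)


def pq_class_image(match: MatchResult) -> ClassImagePQ:
    """RQ, SQ and PQ for one (class, image) from its match result.

    With no instances at all every value is ``None``; with detections or
    misses but no true positive, PQ and RQ are 0 and SQ is ``None``.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    iou_sum = match.iou_sum
    denom = tp + 0.5 * fp + 0.5 * fn
    if denom == 0:
        return ClassImagePQ(0, 0, 0, 0.0, rq=None, sq=None, pq=None)
    rq = tp / denom
    sq = iou_sum / tp if tp > 0 else None
    pq = iou_sum / denom
    return ClassImagePQ(tp, fp, fn, iou_sum, rq=rq, sq=sq, pq=pq)


def _check_dataset(gts: Sequence[AnnotatedScene], preds: Sequence[AnnotatedScene]) -> None:
    if len(gts) == 0:
        raise UndefinedMetricError("empty dataset")
    if len(gts) != len(preds):
        raise ConfigurationError(
            f"ground-truth and prediction lists differ in length: {len(gts)} vs {len(preds)}"
        )


def aggregate_pq(
    gts: Sequence[AnnotatedScene],
    preds: Sequence[AnnotatedScene],
    threshold: float = 0.5,
    classes: Sequence[int] | None = None,
) -> AggregatePQ:
    """Both aggregate PQ values over an index-aligned dataset of scene pairs.

    ``classes`` fixes the class universe for the pooled aggregation;
    by default it is the union of classes present anywhere in the dataset.
    """
    _check_dataset(gts, preds)
    per_image: list[float] = []
    per_image_counts: list[int] = []
    pooled: dict[int, list[float]] = {}
    seen_classes: set[int] = set()

    for idx, (gt, pred) in enumerate(zip(gts, preds)):
        matches = match_all_classes(gt, pred, threshold=threshold)
        seen_classes.update(matches)
        image_pqs = []
        for c, m in matches.items():
            stats = pooled.setdefault(c, [0, 0, 0, 0.0])
            stats[0] += m.tp
            stats[1] += m.fp
            stats[2] += m.fn
            stats[3] += m.iou_sum
            cip = pq_class_image(m)
            if cip.pq is None:
                continue  # class absent from both gt and pred of this image
            if cip.tp == 0:
                logger.info(
                    "image %d class %d has no true positives; PQ contributes 0", idx, c
                )
            image_pqs.append(cip.pq)
        if not image_pqs:
            logger.warning("image %d has no classes present; excluded from aPQ", idx)
            continue
        per_image.append(float(np.mean(image_pqs)))
        per_image_counts.append(len(image_pqs))

    if not per_image:
        raise UndefinedMetricError("no image in the dataset contains any instance")

    universe = sorted(classes) if classes is not None else sorted(seen_classes)
    per_class_pooled: dict[int, float] = {}
    for c in universe:
        tp, fp, fn, iou_sum = pooled.get(c, [0, 0, 0, 0.0])
        denom = tp + 0.5 * fp + 0.5 * fn
        if denom == 0:
            logger.warning("class %d absent from the whole dataset; pooled PQ coerced to 0", c)
            per_class_pooled[c] = 0.0
        else:
            per_class_pooled[c] = iou_sum / denom

    return AggregatePQ(
        apq=float(np.mean(per_image)),
        mpq=float(np.mean(list(per_class_pooled.values()))),
        per_image=per_image,
        per_class_pooled=per_class_pooled,
        n_images=len(per_image),
        classes=universe,
        per_image_class_counts=per_image_counts,
    )


def apq(gts, preds, threshold: float = 0.5, classes=None) -> AggregatePQ:
    """Per-image-averaged multi-class PQ (see :func:`aggregate_pq`)."""
    return aggregate_pq(gts, preds, threshold=threshold, classes=classes)


def mpq(gts, preds, threshold: float = 0.5, classes=None) -> AggregatePQ:
    """Dataset-pooled multi-class PQ (see :func:`aggregate_pq`)."""
    return aggregate_pq(gts, preds, threshold=threshold, classes=classes)


def pq_table(
    gts: Sequence[AnnotatedScene],
    preds: Sequence[AnnotatedScene],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-(image, class) PQ rows: image, class, tp, fp, fn, rq, sq, pq.

    Undefined values appear as NaN in the frame (CSV-friendly); the
    in-memory API keeps them as ``None`` via :func:`pq_class_image`.
    """
    _check_dataset(gts, preds)
    rows = []
    for idx, (gt, pred) in enumerate(zip(gts, preds)):
        for c, m in match_all_classes(gt, pred, threshold=threshold).items():
            cip = pq_class_image(m)
            rows.append(
                dict(image=idx, class_label=c, tp=cip.tp, fp=cip.fp, fn=cip.fn,
                     rq=cip.rq, sq=cip.sq, pq=cip.pq)
            )
    return pd.DataFrame(rows)
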