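"""Pixel-set metrics on individual object masks.

An instance mask is a 2-D boolean :class:`numpy.ndarray` in which ``True``
marks the pixels belonging to the object.  Coordinates are 0-based
``(row, col)`` with the origin at the top-left corner; masks are treated as
pixel sets, not polygons, because all inputs arrive as integer label maps.

The module provides the two equivalent formulations of the Intersection
over Union (set form and per-pixel TP/FP/FN form), the analytic
over-/under-estimation forms ``IoU+ = TP/(TP+n)`` and
``IoU- = (TP-n)/(TP+n)``, boundary extraction, the symmetric Hausdorff
distance between boundaries, and centroids.  Everything here is pure
computation on individual masks; scene-level matching lives in
:mod:`iscmetrics.panoptic` and :mod:`iscmetrics.matching`.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .exceptions import DimensionError, UndefinedMetricError

__all__ = [
    "PixelOverlapCounts",
    "pixel_overlap",
    "iou",
    "iou_over",
    "iou_under",
    "contour",
    "contour_points",
    "hausdorff",
    "centroid",
]

#: 3x3 cross (4-connectivity) structuring element.
CROSS = ndimage.generate_binary_structure(2, 1)


class PixelOverlapCounts(NamedTuple):
    """Per-pixel true/false positive/negative counts between two masks.

    ``tp + fn`` equals the ground-truth area and ``tp + fp`` the predicted
    area, so the counts fully determine IoU.
    """

    tp: int
    fp: int
    fn: int


def _as_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise DimensionError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool, copy=False)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")


def pixel_overlap(g: np.ndarray, p: np.ndarray) -> PixelOverlapCounts:
    """Exact per-pixel TP/FP/FN counts between ground truth ``g`` and prediction ``p``.

    TP are pixels in both masks, FP pixels only in ``p``, FN pixels only in
    ``g`` (set intersection / difference cardinalities).
    """
    g = _as_mask(g)
    p = _as_mask(p)
    _check_same_shape(g, p)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(p)) - tp
    fn = int(np.count_nonzero(g)) - tp
    return PixelOverlapCounts(tp=tp, fp=fp, fn=fn)


def iou(g: np.ndarray, p: np.ndarray) -> float:
    """Intersection over Union (Jaccard index) of two masks.

    Equals ``tp / (tp + fp + fn)`` of :func:`pixel_overlap`.  Raises
    :class:`UndefinedMetricError` when both masks are empty (callers must
    filter empty instances first); returns 0.0 whenever the intersection is
    empty but at least one mask is not.
    """
    counts = pixel_overlap(g, p)
    union = counts.tp + counts.fp + counts.fn
    if union == 0:
        raise UndefinedMetricError("IoU of two empty masks is undefined")
    return counts.tp / union


def iou_over(tp: int, n: int) -> float:
    """IoU of a perfect prediction grown by ``n`` background pixels: ``TP/(TP+n)``.

    The added pixels only enter the union, so size overestimation is
    penalised once.
    """
    if tp <= 0:
        raise UndefinedMetricError(f"iou_over requires tp > 0, got {tp}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return tp / (tp + n)


def iou_under(tp: int, n: int) -> float:
    """IoU of a perfect prediction shrunk by ``n`` object pixels: ``(TP-n)/(TP+n)``.

    Removed pixels leave the intersection *and* become false negatives, so
    size underestimation is penalised twice — the asymmetry that makes IoU
    harsher on eroded than on dilated boundaries.
    """
    if tp <= 0:
        raise UndefinedMetricError(f"iou_under requires tp > 0, got {tp}")
    if not 0 <= n < tp:
        raise UndefinedMetricError(f"iou_under requires 0 <= n < tp, got n={n}, tp={tp}")
    return (tp - n) / (tp + n)


def contour(m: np.ndarray) -> np.ndarray:
    """Boundary of a mask: its pixels having at least one 4-neighbour outside.

    Pixels on the image edge count their out-of-image neighbours as
    outside, so an instance touching the border contributes its border
    pixels to the contour.  Returns a boolean mask of the same shape.
    """
    m = _as_mask(m)
    if not m.any():
        raise UndefinedMetricError("contour of an empty mask is undefined")
    interior = ndimage.binary_erosion(m, structure=CROSS, border_value=0)
    return m & ~interior


def contour_points(m: np.ndarray) -> np.ndarray:
    """``(n, 2)`` float array of (row, col) boundary-pixel coordinates."""
    return np.argwhere(contour(m)).astype(float)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between the contours of two masks, in pixels.

    Maximum over either contour of the Euclidean distance to the closest
    point of the other contour (distances between boundary-pixel centres).
    Zero iff the contours coincide.
    """
    a = _as_mask(a)
    b = _as_mask(b)
    _check_same_shape(a, b)
    ca = contour_points(a)
    cb = contour_points(b)
    d_ab = directed_hausdorff(ca, cb)[0]
    d_ba = directed_hausdorff(cb, ca)[0]
    return float(max(d_ab, d_ba))


def centroid(m: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean of the pixel coordinates of a mask, as (row, col)."""
    m = _as_mask(m)
    if not m.any():
        raise UndefinedMetricError("centroid of an empty mask is undefined")
    coords = np.argwhere(m)
    r, c = coords.mean(axis=0)
    return float(r), float(c)
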