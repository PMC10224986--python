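"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — double loops over pixels and
all-pairs scans — so it shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_overlap(g: np.ndarray, p: np.ndarray) -> tuple[int, int, int]:
    """(tp, fp, fn) by looping over every pixel."""
    tp = fp = fn = 0
    for r in range(g.shape[0]):
        for c in range(g.shape[1]):
            if g[r, c] and p[r, c]:
                tp += 1
            elif p[r, c]:
                fp += 1
            elif g[r, c]:
                fn += 1
    return tp, fp, fn


def brute_iou(g: np.ndarray, p: np.ndarray) -> float:
    tp, fp, fn = brute_overlap(g, p)
    return tp / (tp + fp + fn)


def brute_contour(m: np.ndarray) -> set[tuple[int, int]]:
    """Pixels of m with at least one 4-neighbour outside m (image edge = outside)."""
    h, w = m.shape
    out = set()
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    out.add((r, c))
                    break
    return out


def brute_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """All-pairs max-min Euclidean distance between the two contours."""
    ca = brute_contour(a)
    cb = brute_contour(b)

    def directed(src, dst):
        return max(min(math.dist(s, d) for d in dst) for s in src)

    return max(directed(ca, cb), directed(cb, ca))


def brute_erode(m: np.ndarray) -> np.ndarray:
    """4-neighbourhood erosion by per-pixel scan (image edge = outside)."""
    h, w = m.shape
    out = np.zeros_like(m)
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            ok = True
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def brute_strict_match(gt_masks: dict, pred_masks: dict, threshold: float = 0.5):
    """All-pairs strict-IoU matching: every pair with IoU > threshold."""
    pairs = []
    for g, gm in gt_masks.items():
        for p, pm in pred_masks.items():
            tp, fp, fn = brute_overlap(gm, pm)
            if tp == 0:
                continue
            val = tp / (tp + fp + fn)
            if val > threshold:
                pairs.append((g, p, val))
    return sorted(pairs)


def random_blob(rng: np.random.Generator, shape: tuple[int, int], n_px: int) -> np.ndarray:
    """Connected random blob of exactly n_px pixels grown from a seed pixel."""
    h, w = shape
    m = np.zeros(shape, dtype=bool)
    r = int(rng.integers(h))
    c = int(rng.integers(w))
    m[r, c] = True
    frontier = [(r, c)]
    while m.sum() < n_px and frontier:
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < h and 0 <= c + dc < w and not m[r + dr, c + dc]]
        if not nbrs:
            frontier.pop(idx)
            continue
        rr, cc = nbrs[int(rng.integers(len(nbrs)))]
        m[rr, cc] = True
        frontier.append((rr, cc))
    return m
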