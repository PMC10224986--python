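"""The :class:`AnnotatedScene` container and label-map utilities.

A scene is one image's worth of annotation: an integer instance-ID map
(0 = background, any positive integer = one instance; IDs need not be
contiguous), a mapping from instance ID to class label in ``{1..m}``, and
an optional binary mask of "ambiguous" regions to exclude from evaluation.
Instances cannot overlap because the map is single-valued.  Instances are
taken from the ID map verbatim: no connected-components relabelling is
applied, so a fragmented instance stays a single instance (this preserves
annotator intent when an annotation is split by an occlusion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DimensionError, FormatError

logger = logging.getLogger(__name__)

__all__ = ["AnnotatedScene", "overlap_table", "instance_areas"]


@dataclass
class AnnotatedScene:
    """Instance-ID map plus per-instance class labels for one image.

    Parameters
    ----------
    instance_map:
        2-D integer array; 0 is background, each positive value one instance.
    class_of:
        Mapping from instance ID to class label (positive integer). Every
        nonzero value of ``instance_map`` must have an entry.
    ambiguous_mask:
        Optional boolean array marking regions to exclude from evaluation.
    """

    instance_map: np.ndarray
    class_of: dict[int, int] = field(default_factory=dict)
    ambiguous_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.instance_map = np.asarray(self.instance_map)
        if self.instance_map.ndim != 2:
            raise DimensionError(
                f"instance map must be 2-D, got shape {self.instance_map.shape}"
            )
        if not np.issubdtype(self.instance_map.dtype, np.integer):
            raise FormatError(
                f"instance map must be integer-valued, got dtype {self.instance_map.dtype}"
            )
        if self.ambiguous_mask is not None:
            self.ambiguous_mask = np.asarray(self.ambiguous_mask).astype(bool)
            if self.ambiguous_mask.shape != self.instance_map.shape:
                raise DimensionError("ambiguous mask shape differs from instance map")
        missing = [i for i in self.instance_ids() if i not in self.class_of]
        if missing:
            raise FormatError(f"instances without a class label: {missing[:10]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.instance_map.shape

    def instance_ids(self) -> list[int]:
        """Sorted IDs of the instances present in the map."""
        ids = np.unique(self.instance_map)
        return [int(i) for i in ids if i != 0]

    def areas(self) -> dict[int, int]:
        """Pixel area of each instance present in the map."""
        return instance_areas(self.instance_map)

    def mask(self, instance_id: int) -> np.ndarray:
        """Boolean mask of one instance."""
        return self.instance_map == instance_id

    def classes_present(self) -> list[int]:
        """Sorted class labels that have at least one instance in the map."""
        return sorted({self.class_of[i] for i in self.instance_ids()})

    def class_map(self) -> np.ndarray:
        """Per-pixel class-label map derived from the instance map (0 = background)."""
        ids = self.instance_ids()
        if not ids:
            return np.zeros(self.shape, dtype=np.int32)
        lut = np.zeros(max(ids) + 1, dtype=np.int32)
        for i in ids:
            lut[i] = self.class_of[i]
        return lut[self.instance_map]

    def without_ambiguous(self, extra_mask: np.ndarray | None = None) -> "AnnotatedScene":
        """Copy of the scene with ambiguous-region pixels removed from every instance.

        Instances emptied by the removal are dropped entirely (their IDs
        disappear from the map; ``class_of`` is left untouched and simply
        carries unused entries).  ``extra_mask`` is OR-ed with the scene's
        own ambiguous mask, which lets a caller apply the union of the
        ground-truth and prediction exclusion regions to both scenes.
        """
        mask = self.ambiguous_mask
        if extra_mask is not None:
            mask = extra_mask if mask is None else (mask | extra_mask)
        if mask is None or not mask.any():
            return replace(self, ambiguous_mask=None)
        before = set(self.instance_ids())
        new_map = self.instance_map.copy()
        new_map[mask] = 0
        dropped = before - {int(i) for i in np.unique(new_map) if i != 0}
        if dropped:
            logger.info("ambiguous-region removal emptied %d instance(s): %s",
                        len(dropped), sorted(dropped)[:10])
        return AnnotatedScene(new_map, dict(self.class_of), ambiguous_mask=None)


def instance_areas(label_map: np.ndarray) -> dict[int, int]:
    """Pixel counts of every nonzero label in an integer map."""
    ids, counts = np.unique(label_map, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}


def overlap_table(a_map: np.ndarray, b_map: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel-overlap counts between every pair of instances of two label maps.

    Returns ``{(id_a, id_b): |a ∩ b|}`` for all pairs with nonzero overlap
    and both IDs nonzero.  Computed in one pass over the jointly-nonzero
    pixels, so it scales with image size, not with the number of pairs.
    """
    if a_map.shape != b_map.shape:
        raise DimensionError(f"label map shapes differ: {a_map.shape} vs {b_map.shape}")
    both = (a_map > 0) & (b_map > 0)
    if not both.any():
        return {}
    pairs = np.stack([a_map[both], b_map[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}
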