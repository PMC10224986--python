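"""Synthetic nuclei scenes with controllable detection/segmentation/classification error.

The generator emulates the statistical structure that the evaluation
analyses rely on, without attempting photorealism: a multi-class nucleus
population with class-specific, right-skewed pixel-area distributions;
non-overlapping instances separated by a minimum gap; and "predictions"
derived from the ground truth by dropping instances (missed detections),
eroding/dilating/jittering their boundaries (segmentation error), flipping
their class labels (misclassification), and adding background blobs
(spurious detections).

The default population mirrors the four nucleus classes of a typical
40x (0.25 µm/px) H&E test set: lymphocytes (median area 266 px,
IQR 221–314), neutrophils (546 px, 468–627), epithelial nuclei
(683 px, 524–858) and macrophages (1734 px, 1032–3152).  Areas are drawn
from a log-normal fitted to (median, quartiles) — chosen for positivity
and right skew — and shapes are mildly eccentric ellipses by default
(nuclei are roughly elliptical), with pure discs and star-convex irregular
polygons available for controlled geometry studies.

All generation is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from .exceptions import CapacityError, ConfigurationError
from .perturb import erode1, dilate1
from .scene import AnnotatedScene

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusClassSpec",
    "PopulationSpec",
    "DegradationSpec",
    "RaterSpec",
    "MONUSAC_LIKE_CLASSES",
    "generate_scene",
    "degrade",
    "simulate_raters",
]

#: Normal quantile at 0.75, used to fit log-normal spread from quartiles.
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class NucleusClassSpec:
    """One nucleus class: label, name, population frequency and area quartiles (px)."""

    label: int
    name: str
    frequency: float
    median_area: float
    area_quartiles: tuple[float, float]

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal with this median and interquartile range."""
        q1, q3 = self.area_quartiles
        if not 0 < q1 < q3:
            raise ConfigurationError(f"bad quartiles for class {self.name}: {self.area_quartiles}")
        mu = math.log(self.median_area)
        sigma = math.log(q3 / q1) / (2 * _Z75)
        return mu, sigma


#: Four-class population modelled on a 40x H&E nucleus test set.  The
#: frequencies reflect the strong class imbalance of such sets (lymphocytes
#: and epithelial nuclei abundant, neutrophils and macrophages rare).
MONUSAC_LIKE_CLASSES = (
    NucleusClassSpec(1, "epithelial", 0.40, 683.0, (524.0, 858.0)),
    NucleusClassSpec(2, "lymphocyte", 0.45, 266.0, (221.0, 314.0)),
    NucleusClassSpec(3, "neutrophil", 0.10, 546.0, (468.0, 627.0)),
    NucleusClassSpec(4, "macrophage", 0.05, 1734.0, (1032.0, 3152.0)),
)


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one ground-truth scene.

    ``shape_family`` is one of ``disc``, ``ellipse`` (default; aspect ratio
    drawn uniformly in [0.65, 0.95]) or ``star`` (star-convex radial
    polygon with per-vertex radius noise, for shape-irregularity studies).
    ``min_gap`` is the minimum pixel separation between instances.
    """

    classes: tuple[NucleusClassSpec, ...] = MONUSAC_LIKE_CLASSES
    n_instances: int = 500
    image_shape: tuple[int, int] = (1024, 1024)
    shape_family: str = "ellipse"
    min_gap: int = 2
    star_irregularity: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(c.frequency for c in self.classes)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigurationError(f"class frequencies must sum to 1, got {total}")
        if self.min_gap < 0:
            raise ConfigurationError("min_gap must be >= 0")
        if self.shape_family not in ("disc", "ellipse", "star"):
            raise ConfigurationError(f"unknown shape family {self.shape_family!r}")


def _rasterize_shape(
    family: str, area: float, rng: np.random.Generator, irregularity: float
) -> np.ndarray:
    """Small boolean patch containing one nucleus of roughly the given area."""
    r0 = math.sqrt(area / math.pi)
    if family == "disc":
        size = int(2 * r0 + 5)
        patch = np.zeros((size, size), dtype=bool)
        rr, cc = draw.disk((size / 2, size / 2), r0, shape=patch.shape)
        patch[rr, cc] = True
    elif family == "ellipse":
        q = rng.uniform(0.65, 0.95)  # minor/major aspect ratio
        a = r0 / math.sqrt(q)
        b = r0 * math.sqrt(q)
        theta = rng.uniform(0, math.pi)
        size = int(2 * a + 5)
        patch = np.zeros((size, size), dtype=bool)
        rr, cc = draw.ellipse(size / 2, size / 2, a, b, shape=patch.shape, rotation=theta)
        patch[rr, cc] = True
    else:  # star-convex irregular polygon
        k = int(rng.integers(8, 16))
        angles = np.sort(rng.uniform(0, 2 * math.pi, size=k))
        radii = r0 * (1 + irregularity * rng.standard_normal(k))
        radii = np.clip(radii, 0.3 * r0, 2.0 * r0)
        size = int(2 * radii.max() + 5)
        rows = size / 2 + radii * np.sin(angles)
        cols = size / 2 + radii * np.cos(angles)
        patch = np.zeros((size, size), dtype=bool)
        rr, cc = draw.polygon(rows, cols, shape=patch.shape)
        patch[rr, cc] = True
    # trim to the tight bounding box
    rows_any = patch.any(axis=1)
    cols_any = patch.any(axis=0)
    return patch[np.ix_(rows_any, cols_any)]


def _place_instances(
    patches: list[np.ndarray],
    image_shape: tuple[int, int],
    min_gap: int,
    rng: np.random.Generator,
    max_retries: int = 200,
    occupancy: np.ndarray | None = None,
    instance_map: np.ndarray | None = None,
    start_id: int = 1,
    skip_on_failure: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Drop patches onto the image at random non-overlapping positions.

    Patches are tried largest-first (easier packing); positions are
    rejected while the patch, inflated by ``min_gap``, touches occupied
    pixels.  After too many rejections either raises
    :class:`CapacityError` naming the achievable count, or — with
    ``skip_on_failure`` — records ID 0 for that patch and continues.
    """
    H, W = image_shape
    if instance_map is None:
        instance_map = np.zeros(image_shape, dtype=np.int32)
    if occupancy is None:
        occupancy = instance_map > 0
    order = sorted(range(len(patches)), key=lambda i: -patches[i].size)
    ids = [0] * len(patches)
    next_id = start_id
    placed = 0
    for i in order:
        patch = patches[i]
        if min_gap > 0:
            inflated = ndimage.binary_dilation(np.pad(patch, min_gap), iterations=min_gap)
            pad = min_gap
        else:
            inflated = patch
            pad = 0
        h, w = patch.shape
        if h > H or w > W:
            raise CapacityError(f"instance of size {patch.shape} exceeds image {image_shape}")
        for _ in range(max_retries):
            r = int(rng.integers(0, H - h + 1))
            c = int(rng.integers(0, W - w + 1))
            ir0, ic0 = max(r - pad, 0), max(c - pad, 0)
            ir1, ic1 = min(r + h + pad, H), min(c + w + pad, W)
            infl = inflated[ir0 - (r - pad):ir1 - (r - pad), ic0 - (c - pad):ic1 - (c - pad)]
            if not (occupancy[ir0:ir1, ic0:ic1] & infl).any():
                region = instance_map[r:r + h, c:c + w]
                region[patch] = next_id
                occupancy[r:r + h, c:c + w] |= patch
                ids[i] = next_id
                next_id += 1
                placed += 1
                break
        else:
            if skip_on_failure:
                logger.warning("could not place a %s patch; skipping it", patch.shape)
                continue
            raise CapacityError(
                f"could only place {placed} of {len(patches)} instances in "
                f"{image_shape} at gap {min_gap}; use a larger image"
            )
    return instance_map, ids


def generate_scene(spec: PopulationSpec, seed: int | None = None) -> AnnotatedScene:
    """Generate one non-overlapping ground-truth scene from a population spec.

    Class labels are drawn from the population frequencies and areas from
    the per-class log-normal distributions; for 200 or more instances per
    class the empirical per-class median areas land within 10% of the
    specified medians.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    freqs = np.array([c.frequency for c in spec.classes])
    choices = rng.choice(len(spec.classes), size=spec.n_instances, p=freqs)
    patches = []
    labels = []
    for ci in choices:
        cls = spec.classes[ci]
        mu, sigma = cls.lognormal_params()
        area = float(rng.lognormal(mean=mu, sigma=sigma))
        area = max(area, 9.0)  # floor below which rasterization degenerates
        patches.append(_rasterize_shape(spec.shape_family, area, rng, spec.star_irregularity))
        labels.append(cls.label)
    instance_map, ids = _place_instances(patches, spec.image_shape, spec.min_gap, rng)
    class_of = {iid: lab for iid, lab in zip(ids, labels)}
    return AnnotatedScene(instance_map, class_of)


@dataclass(frozen=True)
class DegradationSpec:
    """Controllable error profile for turning a ground truth into a "prediction".

    ``dropout_rate``: probability that an instance is missed entirely.
    ``spurious_rate``: expected number of spurious background blobs per image
    (Poisson-distributed count).
    ``erosion_px`` / ``dilation_px``: fixed boundary shrink/grow in pixels
    (at most one may be nonzero).
    ``erosion_area_fraction``: alternative to ``erosion_px`` — erode each
    instance repeatedly until at least this fraction of its area is gone
    (for small nuclei this takes only 2–3 one-pixel erosions).
    ``boundary_jitter_px``: amplitude of smooth random boundary displacement.
    ``misclassification_rate``: probability of flipping an instance's class
    to a uniformly random other class.
    """

    dropout_rate: float = 0.0
    spurious_rate: float = 0.0
    erosion_px: int = 0
    dilation_px: int = 0
    erosion_area_fraction: float | None = None
    boundary_jitter_px: float = 0.0
    misclassification_rate: float = 0.0
    kernel: str = "cross"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "misclassification_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        shrinkers = (self.erosion_px > 0) + (self.dilation_px > 0) + (
            self.erosion_area_fraction is not None
        )
        if shrinkers > 1:
            raise ConfigurationError("at most one of erosion/dilation may be active")
        if self.erosion_area_fraction is not None and not 0 < self.erosion_area_fraction < 1:
            raise ConfigurationError("erosion_area_fraction must be in (0, 1)")


def _jitter_mask(mask: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Displace a mask boundary by smooth random noise of the given amplitude (px).

    Adds a Gaussian-filtered noise field, rescaled to unit standard
    deviation then multiplied by ``amplitude``, to the signed Euclidean
    distance function of the mask and rethresholds at zero.  The result can
    fragment; fragments stay part of the same instance.
    """
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=2.0)
    std = noise.std()
    if std > 0:
        noise = noise * (amplitude / std)
    return (signed + noise) > 0


def _erode_to_fraction(mask: np.ndarray, fraction: float, kernel: str) -> tuple[np.ndarray, int]:
    """Erode repeatedly until at least ``fraction`` of the area is removed."""
    target = (1.0 - fraction) * np.count_nonzero(mask)
    steps = 0
    while np.count_nonzero(mask) > target and mask.any():
        mask = erode1(mask, kernel=kernel)
        steps += 1
    return mask, steps


def _padded_bbox(sl, pad: int, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    r0 = max(sl[0].start - pad, 0)
    c0 = max(sl[1].start - pad, 0)
    r1 = min(sl[0].stop + pad, shape[0])
    c1 = min(sl[1].stop + pad, shape[1])
    return r0, r1, c0, c1


def degrade(
    scene: AnnotatedScene, spec: DegradationSpec, seed: int | None = None
) -> tuple[AnnotatedScene, list[dict]]:
    """Derive a degraded "prediction" scene from a ground truth.

    Each instance is independently dropped with ``dropout_rate``; survivors
    receive the configured boundary degradation and may have their class
    flipped; spurious blobs are then placed on free background.  Returns
    the prediction and a per-instance log of every applied change.
    Surviving instances keep their ground-truth IDs; spurious instances get
    fresh IDs above the ground-truth maximum.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    H, W = scene.shape
    pred_map = np.zeros((H, W), dtype=np.int32)
    class_of: dict[int, int] = {}
    log: list[dict] = []
    all_classes = sorted({scene.class_of[i] for i in scene.instance_ids()})
    objects = ndimage.find_objects(scene.instance_map)
    pad = max(int(spec.dilation_px) + 1, int(math.ceil(3 * spec.boundary_jitter_px)) + 2, 2)

    for iid in scene.instance_ids():
        entry: dict = {"instance_id": iid, "class_label": scene.class_of[iid]}
        if rng.random() < spec.dropout_rate:
            entry["dropped"] = True
            log.append(entry)
            continue
        entry["dropped"] = False
        sl = objects[iid - 1]
        r0, r1, c0, c1 = _padded_bbox(sl, pad, (H, W))
        mask = scene.instance_map[r0:r1, c0:c1] == iid

        if spec.erosion_area_fraction is not None:
            mask, steps = _erode_to_fraction(mask, spec.erosion_area_fraction, spec.kernel)
            entry["erosion_steps"] = steps
        elif spec.erosion_px > 0:
            for _ in range(spec.erosion_px):
                mask = erode1(mask, kernel=spec.kernel) if mask.any() else mask
            entry["erosion_steps"] = spec.erosion_px
        elif spec.dilation_px > 0:
            for _ in range(spec.dilation_px):
                mask = dilate1(mask, kernel=spec.kernel)
            entry["dilation_steps"] = spec.dilation_px
        if spec.boundary_jitter_px > 0 and mask.any():
            mask = _jitter_mask(mask, spec.boundary_jitter_px, rng)
            entry["jittered"] = True
        if not mask.any():
            entry["emptied"] = True
            log.append(entry)
            continue

        label = scene.class_of[iid]
        if len(all_classes) > 1 and rng.random() < spec.misclassification_rate:
            others = [c for c in all_classes if c != label]
            label = int(others[rng.integers(len(others))])
            entry["misclassified_as"] = label
        region = pred_map[r0:r1, c0:c1]
        region[mask & (region == 0)] = iid
        class_of[iid] = label
        log.append(entry)

    # spurious detections: blobs drawn from the smallest-area class present,
    # placed on free background (worst case for IoU matching)
    n_spurious = int(rng.poisson(spec.spurious_rate)) if spec.spurious_rate > 0 else 0
    if n_spurious > 0 and all_classes:
        by_label = {c.label: c for c in MONUSAC_LIKE_CLASSES}
        present = [by_label[c] for c in all_classes if c in by_label]
        smallest = min(present, key=lambda c: c.median_area) if present else None
        patches = []
        for _ in range(n_spurious):
            if smallest is not None:
                mu, sigma = smallest.lognormal_params()
                area = max(float(rng.lognormal(mu, sigma)), 9.0)
                sp_label = smallest.label
            else:
                area = 100.0
                sp_label = all_classes[0]
            patches.append((_rasterize_shape("ellipse", area, rng, 0.0), sp_label))
        next_id = max(scene.instance_ids(), default=0) + 1
        _, ids = _place_instances(
            [p for p, _ in patches], (H, W), min_gap=1, rng=rng,
            occupancy=pred_map > 0, instance_map=pred_map, start_id=next_id,
            skip_on_failure=True,
        )
        for (patch, sp_label), iid2 in zip(patches, ids):
            if iid2:
                class_of[iid2] = sp_label
                log.append({"instance_id": iid2, "class_label": sp_label, "spurious": True})

    pred = AnnotatedScene(pred_map, class_of, ambiguous_mask=scene.ambiguous_mask)
    return pred, log


@dataclass(frozen=True)
class RaterSpec:
    """Simulated annotators: per-rater boundary jitter and erosion/dilation bias.

    ``bias_px`` gives each rater's systematic tendency: negative values
    erode (tight annotator), positive dilate (generous annotator), zero is
    unbiased.  ``jitter_px`` may be a single amplitude shared by all raters
    or one amplitude per rater.
    """

    n_raters: int = 2
    jitter_px: float | tuple[float, ...] = 1.0
    bias_px: tuple[int, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_raters < 2:
            raise ConfigurationError("need at least two raters")
        if self.bias_px is not None and len(self.bias_px) != self.n_raters:
            raise ConfigurationError("one bias per rater is required")
        if isinstance(self.jitter_px, tuple) and len(self.jitter_px) != self.n_raters:
            raise ConfigurationError("one jitter amplitude per rater is required")


def simulate_raters(
    scene: AnnotatedScene, spec: RaterSpec, seed: int | None = None
) -> list[AnnotatedScene]:
    """Independent per-rater re-annotations of the same scene.

    Each rater's scene applies that rater's bias (erosion or dilation) and
    an independent smooth boundary jitter to every instance; instance IDs
    are preserved so downstream analyses can validate matches against the
    known identity.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=spec.n_raters)
    raters = []
    for r in range(spec.n_raters):
        bias = 0 if spec.bias_px is None else spec.bias_px[r]
        jitter = (spec.jitter_px[r] if isinstance(spec.jitter_px, tuple)
                  else spec.jitter_px)
        dspec = DegradationSpec(
            erosion_px=max(-bias, 0),
            dilation_px=max(bias, 0),
            boundary_jitter_px=jitter,
        )
        rater_scene, _ = degrade(scene, dspec, seed=int(child_seeds[r]))
        raters.append(rater_scene)
    return raters
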