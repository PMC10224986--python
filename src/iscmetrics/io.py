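"""Reading and writing label-map scenes, plus dataset-style adapters.

Native on-disk format: a pair of single-channel 16-bit integer images —
an instance-ID map (0 = background) and a class map — as PNG or TIFF,
optionally with an ambiguous-region mask and a JSON sidecar naming the
classes.  On read, the class of each instance is the majority class-map
value over its pixels; mixed-class instances are logged (or rejected in
strict mode).

Two read-only adapters cover common dataset layouts: a directory of
per-instance binary masks grouped in class-named subdirectories
(MoNuSAC-challenge style), and a polygon CSV with per-row vertex
coordinate lists (NuCLS style).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import draw

from .exceptions import FormatError
from .scene import AnnotatedScene

logger = logging.getLogger(__name__)

__all__ = [
    "read_label_image",
    "write_label_image",
    "read_scene",
    "write_scene",
    "read_monusac_masks",
    "read_nucls_polygons",
]


def read_label_image(path: str | Path) -> np.ndarray:
    """Read a single-channel integer label image (PNG or TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise FormatError(f"{path}: non-integer pixel values")
    return arr.astype(np.int32)


def write_label_image(arr: np.ndarray, path: str | Path) -> None:
    """Write an integer label map as 16-bit PNG or TIFF (32-bit TIFF if needed)."""
    path = Path(path)
    arr = np.asarray(arr)
    if arr.min() < 0:
        raise FormatError("label maps cannot contain negative values")
    if arr.max() < 2**16:
        out = arr.astype(np.uint16)
    elif path.suffix.lower() in (".tif", ".tiff"):
        out = arr.astype(np.uint32)
    else:
        raise FormatError("labels exceed 16 bits; use TIFF output")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_scene(
    instance_path: str | Path,
    class_path: str | Path,
    ambiguous_path: str | Path | None = None,
    strict: bool = False,
) -> AnnotatedScene:
    """Assemble an :class:`AnnotatedScene` from instance-map and class-map images.

    Each instance's class is the majority class-map value over its pixels
    (class 0 pixels are ignored in the vote).  An instance whose pixels are
    all class 0 is a format error; a mixed-class instance is logged, or
    rejected when ``strict``.
    """
    inst = read_label_image(instance_path)
    cls = read_label_image(class_path)
    if inst.shape != cls.shape:
        raise FormatError(
            f"dimension mismatch: {instance_path} is {inst.shape}, "
            f"{class_path} is {cls.shape}"
        )
    ambiguous = None
    if ambiguous_path is not None:
        amb = read_label_image(ambiguous_path)
        if amb.shape != inst.shape:
            raise FormatError(f"dimension mismatch: {ambiguous_path} is {amb.shape}")
        ambiguous = amb > 0

    class_of: dict[int, int] = {}
    for iid in np.unique(inst):
        if iid == 0:
            continue
        values = cls[inst == iid]
        values = values[values > 0]
        if values.size == 0:
            raise FormatError(f"{instance_path}: instance {iid} has no class pixels")
        labels, counts = np.unique(values, return_counts=True)
        if len(labels) > 1:
            msg = f"{instance_path}: instance {iid} spans classes {labels.tolist()}"
            if strict:
                raise FormatError(msg)
            logger.warning("%s; keeping the majority class", msg)
        class_of[int(iid)] = int(labels[np.argmax(counts)])
    return AnnotatedScene(inst, class_of, ambiguous_mask=ambiguous)


def write_scene(
    scene: AnnotatedScene,
    instance_path: str | Path,
    class_path: str | Path,
    ambiguous_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
    class_names: dict[int, str] | None = None,
) -> None:
    """Write a scene as paired instance/class label images (round-trip safe)."""
    write_label_image(scene.instance_map, instance_path)
    write_label_image(scene.class_map(), class_path)
    if ambiguous_path is not None and scene.ambiguous_mask is not None:
        write_label_image(scene.ambiguous_mask.astype(np.uint8), ambiguous_path)
    if sidecar_path is not None:
        payload = {
            "classes": {str(k): v for k, v in (class_names or {}).items()},
            "n_instances": len(scene.instance_ids()),
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=2))


def read_monusac_masks(
    image_dir: str | Path, class_labels: dict[str, int] | None = None
) -> AnnotatedScene:
    """Adapter for a per-instance binary-mask directory layout.

    ``image_dir`` must contain one subdirectory per class, each holding one
    binary mask image per instance.  Overlapping instance masks are
    resolved in favour of the earlier (lexicographically sorted) file, with
    a warning.  ``class_labels`` maps subdirectory name to class label;
    by default subdirectories are numbered 1..m in sorted order.
    """
    image_dir = Path(image_dir)
    if not image_dir.is_dir():
        raise FormatError(f"not a directory: {image_dir}")
    subdirs = sorted(d for d in image_dir.iterdir() if d.is_dir())
    if not subdirs:
        raise FormatError(f"{image_dir}: no class subdirectories found")
    if class_labels is None:
        class_labels = {d.name: i + 1 for i, d in enumerate(subdirs)}

    instance_map: np.ndarray | None = None
    class_of: dict[int, int] = {}
    next_id = 1
    for d in subdirs:
        label = class_labels.get(d.name)
        if label is None:
            logger.warning("%s: unknown class directory, skipped", d)
            continue
        for mask_file in sorted(d.glob("*")):
            if mask_file.suffix.lower() not in (".png", ".tif", ".tiff"):
                continue
            mask = read_label_image(mask_file) > 0
            if instance_map is None:
                instance_map = np.zeros(mask.shape, dtype=np.int32)
            if mask.shape != instance_map.shape:
                raise FormatError(f"{mask_file}: shape {mask.shape} differs from scene")
            clash = mask & (instance_map > 0)
            if clash.any():
                logger.warning("%s: %d overlapping pixels kept by earlier instance",
                               mask_file, int(clash.sum()))
                mask &= instance_map == 0
            if not mask.any():
                continue
            instance_map[mask] = next_id
            class_of[next_id] = label
            next_id += 1
    if instance_map is None:
        raise FormatError(f"{image_dir}: no mask images found")
    return AnnotatedScene(instance_map, class_of)


def read_nucls_polygons(
    csv_path: str | Path,
    image_shape: tuple[int, int],
    class_labels: dict[str, int] | None = None,
    class_column: str = "group",
    x_column: str = "coords_x",
    y_column: str = "coords_y",
) -> AnnotatedScene:
    """Adapter for a polygon-per-row CSV (NuCLS style).

    Each row holds comma-separated x and y vertex lists and a class name;
    polygons are rasterized onto ``image_shape`` in row order, later rows
    losing any overlapping pixels.  Unknown class names get fresh labels in
    order of first appearance when ``class_labels`` is not given.
    """
    import pandas as pd

    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FormatError(f"no such file: {csv_path}")
    frame = pd.read_csv(csv_path)
    for col in (class_column, x_column, y_column):
        if col not in frame.columns:
            raise FormatError(f"{csv_path}: missing column {col!r}")
    labels = dict(class_labels) if class_labels else {}
    instance_map = np.zeros(image_shape, dtype=np.int32)
    class_of: dict[int, int] = {}
    next_id = 1
    for _, row in frame.iterrows():
        try:
            xs = np.array([float(v) for v in str(row[x_column]).split(",")])
            ys = np.array([float(v) for v in str(row[y_column]).split(",")])
        except ValueError as exc:
            raise FormatError(f"{csv_path}: bad coordinate list in row {next_id}") from exc
        name = str(row[class_column])
        if name not in labels:
            if class_labels is not None:
                logger.warning("%s: unknown class %r, skipped", csv_path, name)
                continue
            labels[name] = len(labels) + 1
        rr, cc = draw.polygon(ys, xs, shape=image_shape)
        keep = instance_map[rr, cc] == 0
        if not keep.any():
            continue
        instance_map[rr[keep], cc[keep]] = next_id
        class_of[next_id] = labels[name]
        next_id += 1
    return AnnotatedScene(instance_map, class_of)
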