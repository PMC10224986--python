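# iscmetrics

Evaluation metrics and diagnostics for **nucleus instance segmentation and
classification (ISC)** in digital pathology.

Challenges and papers in this area often rank algorithms with a single
number, **Panoptic Quality (PQ)**, originally designed for panoptic
segmentation of natural scenes.  On nuclei — tiny objects with fuzzy,
ill-defined boundaries — PQ behaves in ways that are easy to misread: the
strict `IoU > 0.5` matching rule rejects detections a pathologist would
accept, boundary noise alone moves IoU by 10–20 % on the smallest nucleus
classes, and a correctly detected nucleus with the wrong class label is
penalised *more* than a nucleus that was never detected at all.  This
package implements the full PQ stack, the diagnostic experiments that
expose those failure modes, and the separated alternative evaluation
(detection, classification and segmentation scored independently), driven
by a synthetic nuclei-scene generator so that every analysis is
reproducible without any dataset download.

## The metrics

For each class *c* and image *i*, ground-truth instances `G_c = {g_k}` and
predicted instances `P_c = {p_l}` are matched by the strict rule
`IoU(g_k, p_l) > 0.5` (uniqueness of the match is automatic above 0.5).
The matched pairs, unmatched predictions and unmatched ground truths form
the object-level TP/FP/FN sets, and

```
RQ = |TP| / (|TP| + ½|FP| + ½|FN|)       (recognition/detection quality)
SQ = Σ_TP IoU / |TP|                      (segmentation quality)
PQ = SQ × RQ = Σ_TP IoU / (|TP| + ½|FP| + ½|FN|)
```

Two published aggregations are provided: `aPQ` (average over images of the
per-image mean of per-class PQ) and `mPQ` (per-class TP/FP/FN and IoU sums
pooled over the whole dataset before averaging over classes).

The *separated* evaluation replaces the single entangled number with:
detection **F1** on one "nucleus vs background" class (any-overlap or
centroid-distance matching), **balanced accuracy** on the classes of the
matched nuclei, the **Hausdorff distance** between matched contours for
segmentation, and a **sum-of-ranks** aggregation when one final ranking is
needed.

Diagnostics include the analytic over-/under-estimation forms
`IoU⁺ = TP/(TP+n)` and `IoU⁻ = (TP−n)/(TP+n)`, single-pixel
erosion/dilation/shift perturbation sweeps (with 2×-downscale variants
emulating 20× instead of 40× magnification), an object-level confusion
matrix with an explicit background row/column, and the
detection-vs-segmentation error trade-off experiment.

## Worked example

```python
import numpy as np
from iscmetrics import (PopulationSpec, DegradationSpec, generate_scene, degrade,
                        aggregate_pq, match_by_centroid, confusion_isc,
                        detection_f1, balanced_accuracy)

# synthetic four-class nuclei scene and a degraded "prediction"
pop = PopulationSpec(n_instances=300, image_shape=(1024, 1024))
gt = generate_scene(pop, seed=42)
pred, log = degrade(gt, DegradationSpec(dropout_rate=0.1,
                                        boundary_jitter_px=1.0,
                                        misclassification_rate=0.05,
                                        spurious_rate=5.0), seed=43)

agg = aggregate_pq([gt], [pred])
print(f"aPQ = {agg.apq:.3f}, mPQ = {agg.mpq:.3f}")
for c, pq in agg.per_class_pooled.items():
    print(f"  class {c}: pooled PQ = {pq:.3f}")

match = match_by_centroid(gt, pred, radius=15)
conf = confusion_isc(gt, pred, match)
print(f"detection F1 = {detection_f1(conf):.3f}")
print(f"balanced accuracy = {balanced_accuracy(conf):.3f}")
```

Output:

```
aPQ = 0.838, mPQ = 0.838
  class 1: pooled PQ = 0.875
  class 2: pooled PQ = 0.860
  class 3: pooled PQ = 0.859
  class 4: pooled PQ = 0.758
detection F1 = 0.944
balanced accuracy = 0.971
```

The prediction misses 10 % of the nuclei, jitters every boundary by about
one pixel, relabels 5 % of the survivors and adds a handful of spurious
blobs.  PQ folds all of that into one number per class (note how class 4,
the rare macrophage-like class, is hit hardest — a couple of missed
instances among few dominate its RQ).  The separated metrics make the
structure explicit: detection is near-perfect (F1 0.944), classification is
excellent (balanced accuracy 0.971), and the PQ deficit is mostly harmless
one-pixel boundary noise.

A command-line interface exposes the same pipelines
(`iscmetrics evaluate | simulate | perturb | interrater | tradeoff | rank`);
scenes on disk are `<name>.inst.png` / `<name>.class.png` label-image pairs
(16-bit PNG or TIFF), with optional `<name>.ambig.*` exclusion masks.
Read-only adapters for per-instance binary-mask directories and polygon
CSVs are in `iscmetrics.io`.

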