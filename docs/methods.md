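# Methods

This note records the models, conventions and numerical choices behind
`iscmetrics`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scene model

A scene is a single-valued integer **instance-ID map** (0 = background)
plus a mapping from instance ID to class label and an optional binary
**ambiguous-region mask**.  Because the map is single-valued, instances
cannot overlap; IDs need not be contiguous, and no connected-components
relabelling is ever applied — a fragmented annotation remains one instance,
preserving annotator intent.  Coordinates are 0-based `(row, col)` with the
origin top-left; masks are pixel sets, not polygons, because all supported
inputs are label maps.  Before any matching, the union of the ground-truth
and prediction ambiguous masks is removed from *both* scenes, and instances
emptied by the removal are dropped entirely (they are neither matchable nor
counted as misses).

## Panoptic Quality conventions

* **Strict threshold.** A pair matches iff `IoU > 0.5`, strictly: a pair at
  exactly 0.5 is unmatched.  Above 0.5 matches are provably one-to-one,
  which is asserted rather than assumed.  Thresholds below 0.5 are rejected
  (`ConfigurationError`) because they would break that guarantee.
* **Undefined values.** SQ with no true positives, or any of RQ/SQ/PQ for a
  class with no objects at all, is represented as `None` — never NaN, never
  silently 0.  Every coercion to 0 during aggregation is logged.
* **Missing-class policy.** In the per-image aggregation (`aPQ`), a class
  present in exactly one of ground truth/prediction contributes `PQ = 0`
  to that image; a class absent from both is excluded from the image's
  class count `m_i`.  Images with `m_i = 0` are excluded from the image
  count with a warning.  In the pooled aggregation (`mPQ`), a class absent
  from the entire dataset (possible only when the class universe is fixed
  explicitly) contributes 0 with a warning.  These conventions do not
  follow from the PQ definition itself; they are documented choices that
  match common challenge practice.

## Matching rules

Besides strict-IoU matching, two class-agnostic rules are provided:

* **Any-overlap** matching considers every overlapping pair a candidate and
  assigns greedily in descending IoU (so each object gets its largest-IoU
  partner unless already consumed).  This is the loosest useful rule and is
  what the inter-annotator analysis uses.
* **Centroid-distance** matching considers pairs with centroid distance at
  most a tolerance radius (default 15 px at 0.25 µm/px — roughly one
  typical nucleus radius; configurable) and assigns in order of closeness.

All greedy procedures break ties by `(gt ID, pred ID)` lexicographic order,
making the result deterministic and order-independent.  Optimal (Hungarian)
assignment is deliberately out of scope: the evaluated procedures are
greedy by construction.

## Confusion matrix and separated metrics

The object-level confusion matrix for an m-class ISC task is
(m+1) x (m+1) with row/column 0 the background: row 0 holds spurious
predictions, column 0 missed ground truths, and cell (0, 0) is fixed at 0
(there is no countable "correctly predicted background object").  Row sums
1..m are fixed by the ground truth regardless of the predictor, unlike the
matrix total.  Detection F1 collapses all target classes into one
foreground class; balanced accuracy is the mean per-class recall over the
matched-objects submatrix only, so classification quality is measured on
the nuclei that were actually found (classes with no matched object are
excluded with a warning).  Sum-of-ranks assigns rank 1 to the best method
per metric, mid-ranks on ties, and sums across metrics.

## Boundary metrics

Contours are the mask pixels with at least one 4-neighbour outside the
mask; out-of-image neighbours count as outside.  The Hausdorff distance is
the symmetrized directed maximum of Euclidean distances between
boundary-pixel centres (via `scipy.spatial.distance.directed_hausdorff`).
The 4-connectivity boundary definition and pixel-centre distances are fixed
conventions chosen for reproducibility; polygon/sub-pixel geometry and
percentile-HD variants are out of scope.

## Perturbations

The perturbation sweep measures each instance's IoU against its own
perturbed copy, in isolation (no collision handling is needed because the
comparison never involves neighbouring instances):

* `erode1` / `dilate1`: one binary erosion/dilation with the **3x3 cross**
  (4-connectivity) structuring element.  "Single-pixel" does not pin down a
  kernel; the cross is the minimal isotropic choice, and on rasterized
  pixel-centred discs it reproduces the continuous-limit erosion IoU
  `(r−1)²/r²` within +0.023 for radii 5–50, whereas the 3x3 square kernel
  overshoots (deviations to −0.09) because it erodes by √2 diagonally.  The
  kernel is configurable (`cross`/`square`) and recorded in every record.
* `shift1`: the whole map moved one row downward (sign is a fixed
  convention; IoU against the original is direction-invariant), pixels
  shifted past the border lost.
* `downscale2`: nearest-neighbour subsampling at even coordinates —
  deterministic and label-preserving, unlike majority pooling; instances
  emptied by subsampling are dropped with a warning.  The `down2_*` kinds
  perturb in the downscaled space and record post-downscale areas.

The analytic disc oracle `(r−1)²/r²` (valid for r ≥ 2) provides the
independent reference for the erosion sweep in the tests.

## Synthetic data generator

The generator emulates the statistical structure the analyses depend on,
not the appearance of H&E tissue:

* **Classes and areas.** The default population has four classes with the
  per-class median areas and interquartile ranges of a typical 40×
  (0.25 µm/px) nucleus test set: lymphocyte 266 px (221–314), neutrophil
  546 px (468–627), epithelial 683 px (524–858), macrophage 1734 px
  (1032–3152).  Areas are log-normal, fitted in closed form to the median
  (μ = ln median) and quartile ratio (σ = ln(q₃/q₁)/2z₀.₇₅) — chosen for
  positivity and right skew; only medians and IQRs of the real
  distributions are known, so any two-parameter right-skewed family is
  defensible.  Class frequencies (0.40/0.45/0.10/0.05) reflect the strong
  imbalance of such datasets (macrophages and neutrophils rare); they are a
  package choice, not a published statistic.
* **Shapes.** Mildly eccentric ellipses by default (aspect 0.65–0.95,
  random orientation — nuclei are roughly elliptical); pure discs for
  controlled geometry; star-convex radial polygons with per-vertex radius
  noise for shape-irregularity studies.
* **Placement.** Instances are dropped largest-first at uniform random
  positions, rejecting any position where the instance inflated by the
  minimum gap (default 2 px) touches occupied pixels; after bounded retries
  a `CapacityError` names the achievable count.
* **Degradations.** Detection dropout (Bernoulli per instance), spurious
  background blobs (Poisson count, drawn from the smallest-area class —
  the worst case for IoU matching), fixed-pixel erosion/dilation, erosion
  to a target area fraction (repeat 1-px erosions until the cumulative
  loss reaches the target; 30 % loss takes only 2–3 steps on typical
  nuclei), smooth boundary jitter (Gaussian-filtered noise added to the
  signed distance function and rethresholded; amplitude in px of boundary
  displacement), and class flips to a uniformly random other class.
  Survivors keep their ground-truth IDs, so degradation logs and matching
  results can be validated against known identity.
* **Raters.** Simulated annotators are independent jitter draws plus a
  per-rater systematic erosion (tight) or dilation (generous) bias.

Everything is bit-reproducible under a fixed seed
(`numpy.random.default_rng`).

What the generator does **not** model: overlapping or touching nuclei,
texture and staining variation, spatial clustering of classes, annotator
polygon resampling, and correlated errors between instances.  Passing
tests on synthetic data therefore demonstrate properties of the *metrics*
(matching uniqueness, penalty asymmetries, size dependence of IoU), not
the performance of any segmentation algorithm on real tissue.

## Experiment pipelines and problem sizes

Summary statistics follow the boxplot convention: median, quartiles, and
min/max excluding points beyond the Tukey fences (1.5 IQR).  The
inter-annotator analysis fits ordinary least squares of log₁₀(HD) on IoU
over matched pairs with HD > 0 (HD = 0 pairs are excluded from the fit and
counted); which variable to log-transform is not canonical, and this
orientation is flagged as a package choice.  The trade-off experiment
compares a dropout-only prediction with an erosion-to-30 %-area one on the
same scene, scoring both with aPQ/mPQ and with the separated metrics.

Default problem sizes — 800–2 000 instances per scene, images up to
2 816², 10 seeds for the trade-off robustness check — were chosen so that
every sampled median sits well inside its sampling error while the whole
suite and the acceptance script each run in well under a minute of compute
for the heavy parts.

## Known limitations

* The per-pixel analytic forms IoU⁺/IoU⁻ describe idealized uniform
  over-/under-estimation; real boundary errors mix both.
* Balanced accuracy requires at least one matched object and silently
  narrows to the classes that have matches; AUROC is not offered because
  label maps carry no per-class scores.
* The centroid matcher can mismatch when a large and a small nucleus are
  concentric within the radius; the greedy closest-first order makes this
  rare but not impossible.
* `mPQ` over an explicitly fixed class universe treats dataset-absent
  classes as 0, which deflates the average; this mirrors challenge
  practice but is a convention, not a theorem.
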