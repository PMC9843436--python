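# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `milslide`. Everything stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from external measurements.

## The analysis being modeled

The pipeline mirrors a multi-stage histology analysis: whole-slide images
are tiled into patches; patch-level classifiers trained under weak
(slide-level) supervision produce per-patch class probabilities; slide-level
decisions aggregate patch calls; a pixel-level segmenter restricts
downstream tasks to tumor regions; and a survival branch scores each
subject's relative hazard from its patches and partitions the cohort into
three risk groups. All stages run at desk scale on synthetic rasters whose
statistical structure matches what each stage assumes, so every contract is
testable end to end in minutes on one CPU.

## Synthetic slides

A slide is a polygonal region layout rendered with per-class textures:

* **base color** — a stained-background RGB level per class;
* **blobs** — dark elliptical "nuclei" scattered with Poisson counts at
  `spot_density` per 10⁴ px², mean radius `spot_radius_px`, orientations
  drawn around a shared region angle with coherence `anisotropy`;
* **oriented band noise** — sinusoidal stripes along the region angle with
  amplitude proportional to `anisotropy` (the fibrous-stroma signature);
* **pixel noise** — i.i.d. Gaussian with `noise_sd`.

The default palette keeps the background strictly brighter than every
tissue class (so Otsu thresholding works by construction) and separates any
two tissue classes by at least a 25% relative margin in one of
{spot_density, spot_radius_px, anisotropy}; `validate_palette` enforces
both invariants. Classes: background, FP_like, FN_like, stroma, necrosis,
mutant_like, plus an auxiliary "normal" texture.

**Mutation mixing.** A slide's mutation status is realized as texture
mixing: `mutant_fraction` of the tumor area is re-labeled `mutant_like`,
planted as contiguous random disks (each ~1.5% of the tumor area) rather
than i.i.d. pixels, emulating subclonal regions. This makes the patch-level
positive ratio a meaningful dose: the expected fraction of mutant patches
grows with the planted fraction. The realized pixel share lands within
±0.05 of the target (the last disk can overshoot by at most one disk area).

**Survival.** Event times are exponential with rate
`baseline_rate · exp(β · x)` where `x` is the slide's mutant fraction
standardized over the cohort's mixture distribution — so `β` is a per-SD
log hazard ratio with its conventional magnitude (β = 1.5 gives a strong
but not deterministic image–outcome link; β = 0 makes image and outcome
independent by construction). Censoring is an independent exponential plus
a follow-up cap. Defaults: baseline 0.2 events/year (mean event time 5
years), censoring 0.05/year, 20-year cap. Closed forms back the tests
(exponential mean, null log-rank uniformity, negative Kendall correlation
under β > 0).

All generators are pure functions of their spec; one integer seed feeds a
named `numpy.random.Generator` and every raster is byte-reproducible.

## Desk-scale models

No deep-learning framework is used. Every trainable component is a small
numpy model over a fixed bank of local-statistics features (mean luminance,
local SD, dark-pixel density, dark patchiness, edge energy,
structure-tensor orientation coherence, two color-opponent means), with
analytic gradients and a hand-rolled Adam optimizer:

* **segmenter** — per-pixel linear softmax over windowed (15 px) pixel
  features; training loss is weighted categorical cross-entropy plus the
  Lovász-Softmax loss (weight 1.0 by default), with the Lovász gradient
  computed exactly from the sorted-error construction and routed through
  the softmax Jacobian (finite-difference checked in the tests);
* **patch classifier** — one-hidden-layer (24 tanh units) softmax MLP over
  patch summary features, trained under either MIL loss;
* **survival head** — linear scorer on patch features, averaged over a
  subject's patches and squashed by tanh into [−1, 1], trained by the
  Breslow negative log partial likelihood.

The architecture is a pluggable contract: anything mapping patches to
probabilities (or a hazard) can stand behind the same training, ensembling,
and aggregation interfaces. The training contracts keep the full-scale
shape — fixed learning rate, fixed epoch budget (50), early termination on
validation loss (patience 5) — with rates sized for these heads (0.05 for
the linear pixel head; 0.01 Adam for the MLP). The feature bank is fixed,
so training is seconds-fast and bit-reproducible given a seed.

## Numerical and procedural choices

* **Coordinates** are 0-based (row, col) with half-open extents, everywhere.
* **Otsu** maximizes inter-class variance on the 8-bit luminance histogram;
  the reported threshold is the midpoint of the empty gray-level gap above
  the argmax bin (the partition is identical for any cut in the gap); a
  constant image yields an all-background mask with a warning.
* **Patch sampling** is uniform over top-left positions with rejection
  against the fraction filters; the attempt budget is 50× the requested
  count, after which fewer patches are returned with a warning. TMA cores
  are tiled on an overlapping grid (stride = half the window by default;
  the stride is configurable since only "overlapping" is specified).
* **Augmentation** "transpose" is the main-diagonal transpose;
  `expand_with_recipe` orders output originals-first, then ops in recipe
  order. Oversampling takes each patch once before sampling with
  replacement.
* **MIL top-k** keeps `ceil(keep_fraction · n_c)` samples per class within
  each batch (reading "top 70% of each class samples" per batch and per
  class); mean−SD skip uses the population SD (ddof = 0) of the batch's
  true-class scores and multiplier 1.0 by default. An all-skipped batch
  falls back to full-batch cross-entropy with a warning.
* **Positive calls** use per-patch argmax (not a probability cutoff), and
  the ratio-threshold boundary is inclusive: ratio ≥ threshold → positive.
* **Geometric-mean thresholding** searches midpoints of consecutive sorted
  unique validation ratios and breaks ties toward the smallest threshold
  (verified against a dense-grid brute force).
* **Ensembles** select the top k models by validation balanced accuracy
  (ties keep the lower fold index) and average probability outputs; fold
  hazards are averaged (ignoring missing folds) and clipped to [−1, 1].
* **Cox loss** uses Breslow tie handling; the loss is shift-invariant and
  defined as 0 for an event-free batch.
* **Log-rank** is the standard k-sample chi-square on hypergeometric
  variances, implemented vectorized in-package (the cutoff search evaluates
  ~2,000 tests per run) and cross-checked against lifelines to 9 digits on
  shared fixtures; a no-event input returns statistic 0, p = 1.
* **Cutoff lattice** is built by integer indexing (C = (−90 + 5i)/100) to
  avoid float drift: 28 C_L values, 658 pairs, verified by enumeration.
  Risk groups: hazard ≤ C_L → low, ≤ C_H → intermediate, else high. Exact
  p ties prefer smaller C_L, then smaller C_H. Every pair's outcome and
  failure reason is logged in the returned ledger.
* **Censoring rule**: any record extending past the horizon (12 years by
  default) — including an event observed after it — becomes censored at
  the horizon.
* **Weighted IoU** weights per-class IoU by truth pixel fraction; mean IoU
  averages over classes present in the truth; classes absent from both maps
  are excluded. This truth-abundance weighting is one reading of
  "class abundance" weighting; it is the documented convention here.
* **Folds** are class-stratified with disjoint test chunks across folds and
  a seeded train/validation split of the remainder; manifests audit that no
  sample appears in both a fold's train/val and its test set. EFS tertiles
  are near-equal thirds by sorted time (264 → 88/88/88; 88 → 71/17 at the
  default train fraction), with stratified equal-per-group training batches
  available for the survival task.
* **Display rounding** of percentages is half-up to integer percent.

## What the synthetic experiments show — and do not

Passing recovery tests show the *machinery* is correct: the segmenter
reaches mean IoU ≥ 0.9 and the patch classifier ≥ 0.9 accuracy on
high-margin textures; the survival head reaches concordance ≈ 0.8 with a
planted per-SD log hazard ratio of 1.5 and ≈ 0.5 under the null; the
cutoff search recovers planted three-group partitions with multivariate
p < 0.01 in ≥ 8/10 seeds and returns an empty (logged) result when the
constraints are unsatisfiable. These are statements about separable
synthetic textures with planted effects — not about clinical performance.
Real H&E tissue has stain variability, nuclear pleomorphism, scanner
artifacts, and label noise that the generator deliberately omits; the
published clinical accuracies, IoUs, ROC values, and risk-group p-values
are properties of the restricted cohort and full-scale networks and are
out of scope here.

## Problem sizes

Default experiment sizes were chosen as the smallest cohorts at which the
recovery statistics stabilize: 160-px slides, 32-px patches, 18 slides /
3 folds for segmentation, 24 slides for classification tasks, 120 subjects
(20 patches each) for survival, and 10 seeds for the cutoff-recovery rate.
The full test suite runs in about a minute; the acceptance script in under
two.

## Known limitations

* The fixed feature bank is matched to the generator's texture families;
  genuinely new texture classes may need added features (the model
  contract, not the pipeline, is the extension point).
* The mean−SD skip rule's constant and direction, the top-k grouping
  (per class per batch), and the "simple majority" core rule each have
  plausible alternative readings; the chosen conventions are documented
  above and implemented consistently.
* `tumor_fraction` filters use the generator's ground-truth label maps
  rather than a trained segmenter's prediction, isolating each stage's
  evaluation from upstream model error.
* Survival training is full-batch by default; stratified batching is
  available but at desk scale rarely matters.
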