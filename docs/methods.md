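# Methods

## Problem setting

Aortic-valve calcification shows up on parasternal short-axis echocardiograms as
hyperechoic (near-white) deposits on the valve leaflets, inside the dark
sector-shaped ultrasound field.  The pipeline decomposes screening into a detection
stage (where is the valve?) and a classification stage (is the crop calcified?),
with deterministic preprocessing and augmentation around them.  All stages operate
on 8-bit grayscale-replicated RGB rasters with 0-based, half-open pixel boxes
(`width = x_max - x_min`), which removes every off-by-one ambiguity from box
arithmetic and IoU.

## Synthetic scenes: the stated world

`echocalc.synth` renders what the pipeline actually consumes, not ultrasound
physics:

* **Cone**: circular sector, apex near the top edge, axis pointing down,
  half-opening 35° by default, filled with i.i.d. Gaussian speckle
  (mean 70, sd 25, clipped to `[0, speckle_max]`).
* **Valve**: a flat-gray (level 160) annulus with a small seeded radial wobble,
  because the pipeline only needs a localizable structure with an exactly known
  tight box.  Anatomically realistic leaflets would add nothing testable.
* **Calcium**: Gaussian-profiled discs (σ = r/2, support 2r) whose center pixel is
  forced to the exact stated peak, so a threshold test behaves exactly as
  predicted: `calcified(T)` is true iff some blob peak exceeds `T`.
* **Dataset jitter**: valve center uniform within ±10% of the image size, radius
  ±20%, 1–3 peak-255 blobs per calcified sample — enough variation that a detector
  cannot memorize a fixed location.  Default dataset shape: 61 frames,
  22 calcified / 39 healthy (36%), the shape of the clinical cohort this mimics.

`speckle_max` defaults to 200 rather than 255: a 70/25 Gaussian would put a
handful of tail pixels per thousand frames above 220 and make "bright ⇒ calcium"
false at random.  Capping the texture keeps the brightness bands disjoint
(speckle ≤ 200 < calcium band), which is the regime the heuristic is defined for;
set `speckle_max=255` to study its failure mode.

Identical parameters and seed give bit-identical images (NumPy `default_rng`).

**What a green test does not establish**: synthetic rings are high-contrast,
uncluttered and near-separable.  Passing the scaled-down training checks shows the
training/evaluation machinery works and that augmentation+balancing rescue
tiny-data training *on this world*; it says nothing about performance on clinical
frames with probe artifacts, shadowing, neighboring structures or view variation.

## Cone extraction

The sector boundary is two straight edges meeting at the apex plus a far arc.
Detection: threshold the frame (gray > 10), keep the largest connected component,
fill holes, take its 1-px boundary, Hough-vote lines over a 0.25° grid, refine each
candidate by total-least-squares on boundary pixels within 2 px, pick the
best-supported pair separated by ≥ 15°, intersect them for the apex, and set the
radius to the 99.5th percentile of apex–foreground distances (robust to stray
pixels).  The mask is then rasterized analytically from apex/edges/radius, which is
what makes the IoU ≥ 0.95 contract against the true sector achievable even with
speckle.  If no valid line pair is found the convex hull of the bright region is
returned with `fallback=True` — real exports sometimes lack clean boundaries.

Window standardization cuts a fixed 640×640 window centered on the cone centroid
(or a caller-supplied box/center) with zero padding and **no resampling**: every
output pixel equals a source pixel or 0, so gray-level-based downstream logic is
untouched.  Noise reduction subtracts the global scalar minimum over all pixels and
channels (not per-channel), making the darkest zone pure black; it is idempotent.

## Augmentation and dataset assembly

Each operator is deterministic with a fixed parameter pair, giving exactly two
variants per technique per image and the count law `n(1 + 2|T|)`:

| technique  | parameters | box transform |
|---|---|---|
| translation | +0.2 / −0.2 of extent, same signed fraction both axes | integer shift, clip |
| zoom | 0.5 / 2 about the canvas center | corners scaled about center, clip |
| rotation | +10° / −10° about the canvas center | AABB of the four rotated corners, clip |
| gamma | 0.5 / 1.2 | unchanged |

Rotation's ±10° reflects how much probe orientation typically varies between
operators.  Geometry uses pixel-center coordinates (canvas center `(W−1)/2`);
warps are bilinear with zero fill.  The corner-hull box of a rotated *round*
structure overestimates its tight mask box by up to `R(cosθ+sinθ−1)` — inherent to
axis-aligned boxes, tested explicitly rather than hidden.  A transform that empties
a box raises `BoxLostError` with the offending image id.

Balancing duplicates minority samples cyclically (in manifest order) to parity;
duplicates carry `duplicate_of`.  The canonical classification set is built
*balance first, then rotate*: 61 → 78 → 234.

Splitting is a seeded shuffle plus contiguous partition with the remainder
assigned to the training split (61 at 80/10/10 → 49/6/6).  Two leakage policies
exist because augmenting before splitting lets variants of one frame land on both
sides: the default `group_aware=True` path partitions by original-frame group;
the plain path reproduces the augment-then-split procedure.  K-fold gives balanced
fold sizes with the remainder spread over the first folds (61, k=5 → 13/12/12/12/12).

## Models

**Heuristic**: strict binarization (white iff the *minimum* channel exceeds `T`,
so a pixel must be near-white in every channel) and "any white pixel ⇒ calcified".
The reported score is the white-pixel fraction — a convenience, not a calibrated
probability.  Positive calls are non-increasing in `T` by construction.

**Detector**: no deep-learning runtime is available here, so the
pretrained-CNN-plus-fine-tuning design is realized as its classical equivalent: a
sliding-window detector whose window scorer is a logistic model (SGD, log loss)
over 16×16 mean-variance-normalized patches of a letterboxed (aspect-preserving),
4×-downscaled frame.  Training samples one aligned positive window per annotated
box, two 2-px-jittered positives, eight *hard negatives* (the truth window shifted
by ~60% of its size and rescaled ×0.5/×1.7 — these teach localization and size
selectivity) and twelve random negatives with IoU ≤ 0.2.  One shuffled pass over
the sample set per "epoch", with the training log-loss logged per epoch.
Inference scans three scales (0.8/1.0/1.2 × the training median box size) at
stride 2, applies greedy NMS at IoU 0.4 and returns detections above the
confidence threshold (default 0.25).  Ranking uses the raw decision margin — the
sigmoid saturates to exactly 1.0 for well-separated data and would reduce ranking
to ties — while the reported confidence stays in [0, 1].  `select_best` keeps the
single top detection: one aortic valve per short-axis view.

**Classifier**: a frozen convolutional feature extractor — three 3×3
random-filter layers (He-scaled, seeded per backbone name) with ReLU and 2×2 max
pooling on a 64×64 grayscale rendering of the 224×224 ROI — followed by the
configurable pooling mode over the last map (`none` = flatten, `max`/`avg` =
per-channel reduce) and a trainable head: standardize → dense(120, ReLU) →
sigmoid (scikit-learn MLP, Adam, batch size 1, initial step 0.01 — the larger step
is what lets batch-1 training converge within single-digit epoch budgets on tens
of samples).  Six backbone "families" of different widths mirror the relative
capacities of the public EfficientNet/ResNet/MobileNet families they stand in
for; random convolutional features are a standard cheap surrogate for pretrained
features on brightness/texture-separable problems.  Training raises `DataError`
on a single-class manifest (such a head can only echo the majority class).
Classification cutoff is 0.5 with the ≥ convention.

## Numerical choices and degenerate inputs

* Metrics: precision/recall are `None` (flagged), not 0, on zero denominators;
  F1 is computed from unrounded precision/recall.
* Detection matching: greedy one-to-one in descending confidence; at threshold 0
  any positive overlap matches; at threshold 1 only exact boxes match.
* IoU-TP criterion defaults to 0.5 and is exposed as a flag.
* `reduce_noise` on an all-255 image yields all-zero (min subtraction), and
  binarization commutes with it only when the image minimum is already 0.
* Box mapping after affine transforms rounds continuous corners outward
  (floor/ceil), then clips; an emptied box is an error, never a silent drop.
* Seeds: every stochastic routine takes an explicit integer seed; nothing reads
  global RNG state.

## Known limitations

* No physical ultrasound simulation (no beamforming, attenuation, shadowing); the
  generator's speckle is additive Gaussian, not multiplicative Rayleigh.
* DICOM ingestion requires the optional `pydicom` dependency; only pixel data and
  sequential anonymized ids (`STUDY_nnn`) are propagated, never patient metadata.
* The detector's box quantization is the scan stride (8 source px at defaults);
  adequate at IoU 0.5, too coarse for IoU ≥ 0.9 localization studies.
* Patients contributing multiple frames are modeled as independent samples; a
  `patient_id` field exists but no per-patient stratification is implemented.
* The classifier's frozen random features suffice for brightness-separable
  synthetic data; clinical-grade performance would need real pretrained backbones.
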