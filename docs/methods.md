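# Methods

This document describes what `cxrgrade` computes and why the defaults are
what they are. The package grades opacity burden separately for each lung
on a frontal chest radiograph as a 4-class ordinal problem, selects a model
configuration in three stages, and audits the selected model with saliency
concordance and subgroup performance tables. Everything runs end-to-end on
synthetic phantom radiographs with exact ground truth, so every stage is
testable without clinical data.

## 1. The grading task

Each lung receives an ordinal grade from the fraction of its projected area
covered by opacity:

| grade | opacity coverage |
|-------|------------------|
| 0     | none             |
| 1     | 1–33 %           |
| 2     | 34–66 %          |
| 3     | 67–100 %         |

Grades are predicted by two independent classifiers, one per lung side.
Sides use **patient** coordinates throughout: the patient-left lung appears
on the viewer-right half of a frontal radiograph. `phantoms`, `segment`,
and `select` all follow this convention.

## 2. Phantom generator

`phantoms.generate_phantom` renders a deterministic synthetic radiograph
from a `PhantomSpec` (grades, size, seed): a body silhouette, a brighter
spine column, two darker lung fields with per-seed shape jitter, rib
shadows, and additive noise. A grade-`g` lung receives a blobby opacity
whose realized coverage is drawn inside the grade's bin and reported in the
truth record along with exact lung/spine masks. Cohort generation samples
patients with demographic attributes (age, sex, race, COVID status,
inpatient/outpatient), writes PNGs plus sibling `*_mask_*.png` truth masks,
and can inject the artifact types the preparation stage must handle:
duplicate accession copies, photographic negatives, scanned documents, and
pediatric patients.

Realism is deliberately limited: the phantoms capture the *geometry* of the
task (laterality, in-lung opacity, confounding bright structures such as
the spine) and the intensity ordering of tissues, not the texture of real
radiographs. They are sufficient to exercise every pipeline stage and to
make saliency claims falsifiable against exact masks, and nothing more.

## 3. Preparation and exclusions

`prepare.prepare_cohort` reproduces a defensible clinical intake:

* accession de-duplication keeps the earliest acquisition time (optionally
  strict: discard multi-time accessions entirely); rows with missing times
  are routed to a read-error bucket;
* scanned documents, pediatric patients (age < 18), and flagged duplicate
  copies are removed;
* photographic negatives are *inverted in place* rather than dropped;
* an `ExclusionReport` reconciles every input row into survivors plus
  removal categories, and `check()` asserts the arithmetic.

## 4. Segmentation and regions of interest

A small encoder–decoder (`segment.train_segmenter`) learns lung or spine
masks from image/mask pairs at a 64-px internal resolution. Three ROI
schemes feed the classifiers:

* `none` – the full image;
* `lung` – lung-mask crop per side;
* `spine` – the image split into halves along the per-row spine centroid
  (median-filtered; midline fallback when the spine mask is empty).

`normalize_for_net` resizes to the network's input size and scales integer
images by their dtype maximum so absolute brightness cues survive.

## 5. Classifiers and the numerical engine

All networks run on a hand-written NumPy engine (`cxrgrade._nn`): im2col
convolutions, explicit backprop, Adam. Four backbones are available:
`vgg16`, `resnet50`, `chexnet121` (DenseNet-121-style), and `tiny`, a
6-conv from-scratch network used for fast experiments and tests. The head
is shared: an input standardizer frozen on the first large batch, then
Dense(32) → ReLU → Dense(4).

Three `tiny`-specific design choices matter for interpretability:

* **Coordinate ramp channel.** `tiny` prepends a fixed horizontal ramp
  (−1 viewer-left … +1 viewer-right) to its input. Under a global-average-
  pooling head, laterality ("which half am I looking at?") is otherwise
  hard to encode in channel semantics; the ramp makes laterality-selective
  channels learnable, which both helps the sided task and keeps Grad-CAM's
  pooled-gradient channel weighting faithful to the decision.
* **Global average pooling head.** A GAP head is the geometry Grad-CAM's
  channel-weight derivation assumes; `vgg16` keeps its original flattening
  head, the rest pool globally.
* **Decoupled weight decay** (default 10.0 at phantom scale, applied only
  to weight matrices, never biases). Decay suppresses input-independent
  baseline activations in the final feature maps; without it those
  baselines spread Grad-CAM mass uniformly, including outside the lungs.
  The default was chosen on held-out phantoms: decay 100 destroys
  learning, 10 preserves accuracy and localizes saliency.

## 6. Two-stage transfer protocol

`train.fit_two_stage` fine-tunes in two stages:

1. **Stage 1** – all convolutions frozen, head only, lr 1e-3. Features of
   the frozen prefix are computed once and cached, so this stage is cheap.
2. **Stage 2** – unfreeze the last *n* convolutions, lr 1e-4, fresh
   optimizer. For pretrained-style backbones *n* defaults to `T − 5`
   (total minus five), protecting generic early features, with per-backbone
   overrides (`resnet50` 5, `vgg16` 5, `chexnet121` 15). `tiny` is trained
   from scratch and has no pretrained features to protect, so its default
   unfreezes all 6 convolutions.

Both stages use batch 32, plateau LR reduction (patience 7, factor 0.1,
floor 1e-6), early stopping (patience 10), and restore the best-validation
weights. Under the `double` balancing scheme stage 2 trains on the full
(unbalanced) training set; otherwise it reuses the stage-1 rows.

## 7. Balancing

`splits.balance` implements three schemes on the training rows of a fold:

* `under` – subsample every class to the minority count;
* `over` – augment minority classes up to the majority count; augmented
  rows are flagged `synthetic` and carry their sampled transform (rotation
  ±10°, scale 0.9–1.1, translation ±5 %) applied at load time;
* `double` – `under` for stage 1, the full training set for stage 2.

A class with zero rows is an error: balancing cannot invent a class.

## 8. Splits

`make_patient_splits` first sets aside whole patients as an out-of-bag
(OOB) set until a requested image count is reached, then builds 5
patient-level folds at 80/10/10 by patient count. All assignments are by
patient, never by image, so no patient appears in two partitions of any
fold or in both a fold and the OOB set.

## 9. Metrics

* **Macro-averaged MAE**: per-true-class mean absolute grade error,
  averaged unweighted over the classes present (a `strict_k` variant
  always divides by 4). This is the primary selection metric: it respects
  ordinality and is insensitive to class imbalance.
* Weighted precision/recall/F1 (zero-division → 0), R², and binary
  collapses at thresholds t ∈ {1, 2, 3} (grade ≥ t vs below).

## 10. Saliency and the Heatmap Concordance Score

Grad-CAM is computed per class at the last convolution; a per-image
attention map is the probability-weighted average of the four class maps,
and the two sides' maps average into a whole-lung map. The **HCS** of a
heatmap against the lung mask is

* `intensity` mode (default): Σ(mask · heat) / Σ(heat);
* `count` mode: the fraction of non-zero heat pixels inside the mask.

An all-zero map has no defined HCS and raises `UndefinedHCS`. MA-HCS
macro-averages per-image HCS over true grades, mirroring the macro-MAE
axis.

## 11. Three-stage selection

1. **Stage 1** – train the full architecture × balancing × segmentation
   grid on fold 1 only; rank by macro-MAE (ties: higher F1, then
   lexicographic); keep the top 5.
2. **Stage 2** – 5-fold cross-validation of the survivors; report fold
   means ± SD plus MA-HCS and binary collapses; `choose_best` takes the
   equal-weight rank-sum of macro-MAE (ascending) and MA-HCS (descending),
   ties to the lower MAE.
3. **Stage 3** – retrain the winner on a fresh split of the non-OOB data
   and compare on the OOB set against the original reader (OR) and a
   simulated second reader (one ordinal step with 10 % probability),
   giving OOBTR-vs-OR, model-vs-OR, and model-vs-OOBTR metric blocks, plus
   per-subgroup tables over race, sex, and COVID status.

The package ships a 27-row reference stage-1 grid and a 5-row reference
cross-validation table so the selection arithmetic is testable bit-for-bit
without retraining; `select.run_pipeline` produces the same artifacts from
scratch on a phantom cohort.

## 12. Problem sizes and budgets

Defaults were chosen so that a complete demonstration runs on one CPU:
64-px inputs and the `tiny` backbone for pipeline runs, 224-px inputs for
the full-protocol learnability/saliency checks (600 training phantoms,
~2–3 minutes), and a reduced 2×2×2 grid over 2 folds for end-to-end runs
(~1 minute on a 60-patient cohort). These sizes are package choices made
for testability, not claims about clinical-scale training.
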