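# Methods

## Problem and pipeline

A patient recovering from rotator-cuff injury wears a smartwatch while
performing prescribed shoulder exercises, both under physiotherapist
supervision in clinic and unsupervised at home. The watch streams 3-axis
accelerometer (m/s², gravity included) and 3-axis gyroscope (rad/s)
samples at a nominal but irregular ~50 Hz. The analysis question is
twofold: *when* in an at-home record was the patient exercising at all
(everything else — rest, walking, gesturing — is out-of-distribution,
OOD), and *which* exercise was being performed.

The pipeline is two-stage. Stage 1 scores every window with an OOD-ness
score and removes windows above a calibrated threshold; stage 2 classifies
the surviving windows into exercise classes, optionally coarsened by a
motion-grouping taxonomy (18 exercises → 8 motions → 6 simple motions,
each optionally crossed with body position).

## Preprocessing

Streams are linearly interpolated onto an exact 50 Hz grid anchored at the
first sample, with no extrapolation past the last sample. Linear
interpolation is the minimal-assumption choice and is directly testable
against closed-form signals. Timestamp gaps longer than 1 s are treated as
sensor dropouts: the record is split there rather than interpolated
across, so no signal is fabricated.

Windows are 10 s (500 samples) with a 50-sample step (1 s, 90 % overlap).
The step is interpreted in samples, following the sample-based
segmentation convention of common HAR tooling. A window is labelled with a
class only if that class covers a strict majority (> 50 %) of its samples;
ties and sub-majority coverage fall back to the OOD label. The majority
fraction is configurable.

## Features

Ten statistics per channel per window (60 features): median, RMS, SD,
variance, min, max, skewness, excess kurtosis, mean spectral energy, and
mean crossings. Conventions that matter:

* moments use the population denominator L; skewness m₃/m₂^1.5 and excess
  kurtosis m₄/m₂²−3 are defined as 0 when m₂ = 0, so constant windows
  never produce NaN;
* mean spectral energy is the mean over all L DFT bins of |X_k|² (DC
  included), which by Parseval equals L·mean(x²) — this identity is the
  test oracle;
* a mean crossing requires strictly opposite signs of consecutive
  deviations from the channel mean (a sample exactly at the mean does not
  cross), which makes the count deterministic on integer-valued inputs.

Features are z-scored per column with statistics from the training split
only (`standardize: true`, the default; switchable off). Distance-based
methods (KMeans, KNN) are scale-sensitive, and the raw features span
several orders of magnitude, so unstandardized distances would be
dominated by spectral energy. Zero-variance columns map to 0. The same
scaled features feed the random forests (harmless for trees).

## The convolutional network

The deep feature extractor is the standard three-block fully convolutional
network for time series: Conv1d(128, k=8)→BN→ReLU, Conv1d(256, k=5)→BN→
ReLU, Conv1d(128, k=3)→BN→ReLU, global average pooling, linear softmax
head. The pooled 128-wide pre-softmax activation is the *embedding*.
Because pooling is global, the network accepts any window length, which
the unit tests exploit with short windows.

It is implemented directly in numpy (float32) with manual backpropagation:
convolutions evaluated tap-by-tap as batched matrix products (routing the
arithmetic through BLAS), batch norm over the (batch, time) axes with
running inference statistics, and an Adam optimizer with cross-entropy
loss. Training is deterministic given the config seed. Raw windows are
z-normalized per channel with training-split statistics stored on the
model. Reference hyperparameters are batch 256, learning rate 1e-4,
150 epochs; the benchmark and test configurations use a reduced budget
(4–25 epochs, learning rate 1e-3, batch 64, capped training subsamples),
chosen as the package's standard small-scale setting — the calibration
guarantee and all structural invariants are independent of training
budget, and the separable-data checks confirm the optimizer converges.

## OOD detectors

All detectors emit an OOD-ness score (higher = more non-exercise);
exercise is the positive class, kept iff score ≤ τ.

* **KMeans** (engineered or embedding features): distance to the nearest
  centroid of a KMeans fit (10 restarts, seeded) on in-distribution
  training features; the cluster count equals the number of classes at the
  active grouping level, since regrouping classes changes where cluster
  centres should sit.
* **Softmax threshold**: 1 − max softmax probability of the
  in-distribution FCN.
* **Patient-specific KNN**: mean Euclidean distance to the k = 3 nearest
  windows of the patient's *support* session (their most recent supervised
  session). If the support has fewer than k rows, all of it is used, with
  a warning.
* **Proxy-supervised** (random forest, FCN, or patient-KNN base): a proxy
  ADL class, size-matched to the in-distribution data, is added as an
  extra training class; the score is the predicted proxy-class probability
  (equivalently one minus the summed exercise-class probabilities). The
  patient-KNN base scores with the fraction of the k nearest neighbours
  that are proxy rows.

**Threshold calibration.** τ is the smallest observed calibration score
whose coverage of the known-exercise calibration scores reaches the
sensitivity target (0.90) — this maximises specificity subject to the
sensitivity constraint, and the achieved calibration sensitivity is ≥
target by construction. Pooled detectors calibrate on training-split
exercise windows (never the test subject's data, which would leak).
Patient-specific distance detectors calibrate on the support session's own
leave-one-out scores, since each support row's zero self-distance would
otherwise bias τ low; the proxy patient-KNN variant scores the support
rows directly (the fraction-of-neighbours score is not subject to the
zero-distance degeneracy, though self-inclusion does make its calibration
scores slightly optimistic — a known approximation).

## Classifiers

* **Random forest** on engineered features or embeddings, with
  hyperparameters pinned explicitly (100 trees, Gini, √D candidate
  features per split, unlimited depth, bootstrap) so behaviour does not
  drift with library defaults.
* **FCN** trained end-to-end on raw windows.
* **Patient-specific KNN** (k = 3, Euclidean) on the support session;
  majority vote, with a three-way tie resolved by the single nearest
  neighbour (deterministic and distance-consistent).

Labels are mapped to the active grouping level *before* fitting, so each
grouping has its own trained models. A structural invariant is asserted on
every evaluation run: mapping exercise-level predictions to any coarser
grouping can never lower accuracy (a correct fine label stays correct),
so grouped accuracies reported by the pipeline are internally consistent.

## Evaluation protocol

Five-fold cross-validation split **by subject** (seeded shuffle, not
stratified): no window of a test-fold subject ever enters training, and
this is asserted at runtime. Within a test subject, the most recent
supervised session is the test set; the second-to-last is the support
session for patient-specific methods; subjects with fewer than two
sessions are excluded from patient-specific evaluation. Test records whose
class lacks supporting data in an earlier session of the same subject are
excluded — identically for every method, so all methods face the same test
sets.

Clinic-style evaluation pairs a fold's test exercise windows with
size-matched proxy windows as negatives; proxy subjects are split in half
so evaluation negatives are never the proxy rows used in training.
Home-style evaluation scores each home record against its exact
ground-truth mask; records containing no true exercise contribute
specificity only; metrics are averaged per record (a pooled-window AUROC
is reported alongside, labelled distinctly).

AUROC is rank-based (Mann–Whitney, ties 0.5) on the continuous scores, not
the thresholded mask. Fold aggregates report mean and standard error
SD(fold means)/√n with population SD. Per-subject metrics within a fold
are averaged before fold aggregation, because patient-specific detectors
have per-subject thresholds whose raw scores are not pool-comparable.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not shoulder biomechanics:

* **class templates** — a gravity orientation (wrist attitude during the
  exercise) plus 3 harmonic amplitude/phase sets per channel; classes in
  the same simple-motion group share a correlated deviation (weight 0.7
  group, 0.35 class), so grouping genuinely eases classification; the
  separation scalar `sep` multiplies all deviations, with `sep = 0`
  collapsing every class to one template;
* **repetitions** — periods drawn i.i.d. from a lognormal moment-matched
  to mean 3.8 s, SD 2.3 s (right-skewed by construction), the slow cadence
  characteristic of a rotator-cuff patient population;
* **subjects and sessions** — each subject carries a random wrist rotation
  (rotation-vector SD 0.30 rad ≈ 17°, chosen to place pooled grouped
  classification in the high-0.8/low-0.9 accuracy regime reported for
  patient populations) and amplitude scale; each session adds a smaller
  drift (0.12 rad);
* **records** — clinic records are session-long sequences of labelled
  bouts separated by short rests; home records interleave bouts, rest
  (with one guaranteed 120 s near-static stretch) and ADL segments
  (mean-reverting Ornstein–Uhlenbeck motion, with a periodic walking
  regime), with exact masks; timestamps carry ±4 ms jitter to exercise
  resampling;
* **proxy set** — generated from disjoint "proxy subjects" with a heavier
  gesturing/walking mixture than home non-exercise, so the proxy is a
  deliberately imperfect stand-in for the true at-home OOD distribution.

The default benchmark cohort is 20 subjects × 4 sessions × 8 classes
(spanning all 6 simple-motion groups, 4 classes assigned per subject),
fixed seed 7. What the generator does **not** emulate: real biomechanics
and joint constraints, label noise from physiotherapist annotation,
device-specific sensor error models, or patients performing exercises
incorrectly. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative orderings (proxy training
improves OOD detection; grouping improves classification;
patient-specific methods win when inter-subject variability dominates)
emerge under the assumed structure — not that the clinical accuracy
numbers transfer.

## Numerical choices and degenerate inputs

* Records with non-finite rows drop them at read time (count logged);
  fewer than two valid samples is an error.
* Label intervals are half-open [t₀, t₁), so adjacent intervals partition
  cleanly.
* A record shorter than one window yields an empty window set with a
  warning, not an exception.
* Constant feature columns scale to 0; constant channels produce zero
  skew/kurtosis.
* KNN with |support| < k uses the whole support.
* Calibration on an empty score set is an error (the caller must apply the
  support-exclusion rule first).
* Seeds: a single global seed is fanned out per stage via an FNV-1a hash
  of the stage name, keeping stages decorrelated but reproducible; all
  derived seeds are < 2³¹.

## Problem sizes

The shipped benchmark computations use one CV fold with the reduced FCN
budget for the calibration-sensitivity audit (≈ 2 min on one CPU) and five
folds of the engineered-feature random-forest paths for the
detection/classification summary (≈ 1 min, after ≈ 40 s of cohort
generation and featurization ≈ 8 000 clinic / 8 600 home / 1 500 proxy
windows). These sizes are the package's standard small-scale settings;
every quantity they produce is recomputed at run time.
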