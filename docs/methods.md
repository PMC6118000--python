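# Methods

## Problem and model

During sleep a person lies on the left side, the back (supine), the right
side or the stomach (prone). Body position moves and rotates the heart
relative to the chest electrodes, so the projection of the cardiac vector
onto a single lead — and therefore the shape of every beat — changes with
position. `ecgposture` operationalizes one analysis of that phenomenon:
denoise an overnight lead-II ECG sampled at 200 Hz, delineate each beat's
landmark points, condense each beat into 30 morphology features, aggregate
beats into 30-s epochs, quantify per-position feature shifts, and train a
random forest to read the lying position back off the features.

The characteristic signature the pipeline is built around: on the **left
side** the P, R and T waves shrink, the S wave deepens, the S/R
depth-to-height ratio rises and the QRS triangle angle at S narrows, while
the **right side** is nearly indistinguishable from supine apart from a
slightly smaller T wave. Time-interval features move far less than
amplitude features.

## Feature definitions

All amplitudes are measured against the *stable point*: the TP segment
(T end of one beat to P onset of the next, electrically quiet) is smoothed
with a width-5 mean filter, five points are read at the interior fractions
1/6…5/6 of the segment, and their mean is the isoelectric level for the
beat that precedes the segment. The interior fractions avoid contamination
from the T-end / P-onset neighbourhoods; "equal intervals" alone would not
pin the picks down.

Beyond the standard intervals, widths, heights and slopes, three
definitions deserve note:

* **Chord-corrected areas.** The QRS area sums the signal between the Q
  and S peaks after subtracting the straight line (chord) joining the two
  endpoint amplitudes; likewise for the T-wave area between T onset and T
  end. With both endpoints on the baseline this is the plain area; with
  equal sub-baseline endpoints it reduces to the classical
  triangle-subtraction; with unequal endpoints the chord generalizes the
  triangle. Results are magnitudes in mV·ms.
* **S/R** = |S − stable| / (R − stable): the ratio of S-wave *depth* to
  R-wave height. A literal signed ratio would be negative for any
  sub-baseline S; depths are reported as magnitudes throughout (Q and S),
  so S/R, RS = R height + S depth and QR = R height + Q depth are all
  positive.
* **∠QSR**, the interior angle at S of the Q–R–S triangle by the law of
  cosines. The construction mixes a time axis (ms) and a voltage axis
  (mV), so an aspect ratio is unavoidable; the default is **10 ms per mV**
  and it is the single free geometric parameter (`aspect`). Only
  comparisons at a fixed aspect are meaningful.
* **QTc** is Bazett's correction, QT / √(RR in seconds).

Beat vectors are aggregated to the epoch by the per-feature **median**
over the epoch's QC-valid beats (robust to one mis-delineated beat); a
feature with fewer than 10 contributing beats is missing. The 12-feature
classification subset {QT, RR, TP segment, ∠QSR, S/R, QR, P peak, R peak,
T peak, T area, QRS area, T/QRS area ratio} is fixed, adopted from the
reference study's significance screen rather than re-derived.

## Preprocessing

Fixed order: mains filter → wavelet denoising → (coarse R detection →
TP anchors) → baseline removal.

* **Mains**: a one-period moving average (4 samples at 200 Hz / 50 Hz),
  an exact comb null at the mains frequency with < 0.1 % loss at ECG
  frequencies. Even-width windows use a centred kernel with half-weight
  endpoints, so the filter is zero-phase; edges are mirrored. The comb is
  idempotent on the content it is designed for (ECG band + mains line);
  it is *not* idempotent on broadband EMG noise, whose removal belongs to
  the next stage.
* **EMG band**: 3-level dyadic wavelet decomposition (db4 by default),
  the two finest detail bands thresholded at the universal threshold
  σ√(2 ln n), σ from the finest band's median absolute deviation. We use
  translation-invariant (8-shift cycle-spun) **hard** thresholding: soft
  shrinkage at the universal threshold biases the large QRS coefficients
  by the full threshold and, measured on synthetic beats with 0.05 mV
  EMG-band noise, recovers only ~21 % of the noise RMSE, versus ~46 % for
  the cycle-spun hard variant at the same threshold. Mode, levels and
  shift count are configurable. On a clean signal the estimated noise
  floor is ≈ 0, so the stage is a near-identity.
* **Baseline**: a natural cubic spline through one anchor per beat
  (median amplitude in a ±50 ms window at 60 % of the RR interval — the
  middle of the TP segment), held constant beyond the anchor range;
  a polynomial of degree ≤ 3 when fewer than 4 anchors exist. The
  circularity (baseline needs TP anchors, TP needs fiducials) is resolved
  by a two-pass scheme: coarse R detection → anchors → baseline removal →
  full delineation.

## Delineation

R peaks: the squared-gradient envelope smoothed over 30 ms is compared to
an adaptive threshold — per-2-s-block median × 8, floored at 20 % of the
block's 99th percentile (the percentile term rejects P/T envelope lobes,
which carry orders of magnitude less derivative energy than a QRS) — with
a 250 ms refractory distance, refinement to the local signal maximum, and
a search-back pass at 40 % threshold inside RR gaps longer than 1.66× the
median RR.

Q and S are the minima of (−60, 0) and (0, 60] ms windows around R; P and
T peaks the maxima of [−250, −80] ms and [80, min(400, 0.6·RR)] ms
windows, discarded when the deflection from the local baseline (median of
the beat's neighbourhood) is under 0.05 mV. Wave onsets/ends use the
**area-increment rule**: walking from the peak, the boundary is the first
sample whose w-sample look-ahead window holds area below θ·(area of the
window at the peak). Defaults w = 10 samples, θ = 0.01; with θ = 0.05 the
first-window-below-threshold rule stops ~30 ms short on a wide T wave,
while θ = 0.01 lands within ~15 ms on clean signals. On noisy signals the
window area rarely falls below θ·A_peak (the noise floor dominates), so
each boundary search is capped at a physiologic span (P: 80 ms, T:
160 ms, QRS onset: 30 ms) and the J point falls back to S + 20 ms; all
boundaries are clamped into open intervals between their neighbouring
landmarks, which enforces the temporal ordering by construction.

Beat QC replaces the visual check used on real recordings: a beat is
flagged (never deleted) if any of the 11 landmarks is missing, RR ∉
[400, 2000] ms, R height ∉ [0.2, 6] mV, or ordering is violated.

Epochs: each beat belongs to the half-open 30-s epoch containing its R
peak. Excluded from analysis: unlabelled epochs, epochs with < 10 valid
beats (the automatic surrogate for signal disturbed while turning over),
epochs in same-position runs of ≤ 2 epochs (≤ 1 min, too close to a
position change), and — for classification only — prone epochs. The
pointwise rules run before the run rule, making the exclusion idempotent.

## Statistics

The unit of inference is the subject: per-subject per-position feature
means are formed first and each position pair (left–supine, left–right,
supine–right) is compared with a paired two-sided t-test across subjects.
Pooling thousands of autocorrelated epochs would drive every P value to
zero; the subject level is the scale at which the contrast replicates.
All-zero differences report P = 1. Stars: *** ≤ 0.001, ** ≤ 0.01,
* ≤ 0.05; no multiple-testing correction by default (a Benjamini–Hochberg
option exists, off by default).

## Classification

Random forest: 500 trees, bootstrap resamples of size N, fully grown, √M
candidate features per split (M = 12 → 3), majority vote; the per-class
vote fraction is the ROC score. Three schemes:

* **subject-specific** — per subject, stratified 20 %/80 % train/test
  split, 10 repeats with fresh draws;
* **subject-independent raw** — leave-one-subject-out over ≥ 3 subjects;
* **subject-independent normalized** — as above after rescaling every
  subject's features by their own 5 %/95 % quantiles mapped linearly to
  [0, 1] (out-of-span values extrapolate linearly; a constant feature maps
  to 0.5). Fitting per subject is the only scope that can remove a
  subject-level offset for an unseen test subject.

Evaluation: confusion matrices (rows = predicted, columns = true),
accuracy, Cohen's κ = (P_A − P_C)/(1 − P_C) computed in integer
arithmetic with a single final division (bit-exact against a rational
brute force), and one-vs-rest ROC/AUC, sensitivity, specificity and F1
with the other two positions merged into the negative class. Per-class
"accuracy" is reported as sensitivity (recall) and labelled as such.

## Synthetic data

The generator exists to give every stage checkable ground truth; it is
first-class, tested code.

* **Beat model**: five raised-cosine (Hann) bumps — P, Q, R, S, T — on a
  flat baseline. Compact support makes every onset/peak/end closed-form
  and the TP segment exactly isoelectric, so stable-point and boundary
  recovery have well-posed answers; a realistic dynamical ECG model is
  deliberately avoided. Template (centre, half-width, amplitude):
  P(−160, 55, 0.15), Q(−30, 15, −0.10), R(0, 15, 1.20), S(30, 15, −0.25),
  T(300, 130, 0.35); ms/mV; RR 1000 ± 25 ms. Offsets are multiples of
  5 ms so at 200 Hz every landmark falls on the sample grid.
* **Position effects** (defaults; directions are the reported signature,
  magnitudes are generator design, configurable, never asserted as
  empirical): left P×0.60, R×0.75, S×1.25, T×0.70, QT+7 ms, RR+40 ms;
  right T×0.90 only; prone P×0.70, R×0.65, S×0.90, T×0.75, QT−5 ms.
* **Between-subject variability**: log-normal per-wave amplitude factors
  (σ = 0.40) plus Gaussian RR (σ = 60 ms) and QT (σ = 40 ms) offsets. The
  one-σ subject offsets (~40–50 % amplitude, 40 ms QT) deliberately
  exceed the largest position effect (25–30 %, 7 ms), so raw
  cross-subject transfer fails by construction while per-subject
  normalization and within-subject training succeed — the qualitative
  ordering the three schemes are meant to exhibit.
* **Noise**: baseline wander 0.15 mV at 0.25 Hz, EMG-band white noise
  0.03 mV, mains 0.02 mV at 50 Hz — small enough that clean-mode checks
  are exact and large enough to exercise every preprocessing stage.
* **Schedules**: geometric run lengths (mean 30 epochs) over a
  left-dominant prior (left 0.46, supine 0.16, right 0.34, prone 0.04);
  the rare prone epochs exercise the prone-exclusion rule. Sleep stages
  (wake/REM/light/deep ≈ 10/14/67/9 %) are carried as metadata only.
* **Feature-level shortcut**: `sample_feature_table` draws epoch rows
  directly from closed-form template feature values plus 4 % relative
  Gaussian noise (epoch medians over ~30 beats are tight), so the
  statistics and classification stages can be tested at scale without
  signal processing.

What the generator does **not** emulate: ectopy or arrhythmia,
respiratory modulation of amplitudes, double-peaked R waves, multi-lead
structure, gradual position transitions, non-stationary noise. Passing
tests therefore demonstrate correctness of the computation under the
stated morphology model, not clinical performance on real recordings.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 1-hour-per-subject
recordings (≈ 3 450 beats each) for signal-path checks and feature-level
cohorts of 9 subjects × 180 epochs (or one subject × 450–3 000 epochs)
for the classification schemes; significance calibration uses 1 000
replicates of 9-subject null cohorts. These sizes give stable estimates
(binomial SE ≤ 0.7 points on the calibration rate) at interactive run
times. All randomness flows from a single seed through
`numpy.random.default_rng`; reruns are bit-identical. Ties in the
epoch-median aggregation follow numpy's median; quantiles use linear
interpolation; degenerate inputs (missing landmarks, empty epochs,
constant features, single-class training sets) propagate as missing
values or raise, as documented per function.

## Known limitations

* The worked-example confusion matrices are consistency anchors for the
  evaluation formulas; absolute reproduction of the source study's
  feature tables on real recordings is out of scope (and its printed
  units for some amplitude features are internally inconsistent).
* The ∠QSR aspect convention is arbitrary up to the documented default.
* The area-increment boundary has a known early-stop bias that grows with
  θ and shrinks with wave width; boundary accuracy is specified in the
  ±20 ms regime, not at sample resolution.
* EDF/PSG ingestion is not implemented; inputs are the package's plain
  CSV/JSON formats.
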