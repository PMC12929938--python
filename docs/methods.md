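# Methods

## Signal model

A translocation event is a vector of ionic-current samples (pA) at 5 kHz.
The package models two classes:

* **Non-delayed** — a piecewise-constant stepped background (emulating the
  barcode's sequence-dependent current levels) with broadband Gaussian
  within-block noise, plus two short spacer-like excursions: a high spike
  near the event start and a low dip near fractional position 0.97–0.985,
  emulating the current features of the probe's abasic C3 spacers.
* **Delayed** — the same construction with one contiguous plateau starting
  at a drawn fractional position in [0.70, 0.80].  The plateau keeps the
  local mean level; its residual noise is *slow baseline wander* (white
  noise smoothed by a moving average of 151 samples ≈ 30 ms, rescaled to
  1.5 pA SD), not white noise.

The wander model is a deliberate physical choice with a methodological
consequence.  A stalled probe–target duplex suppresses the broadband
translocation noise but leaves low-frequency drift; in the frequency domain
that concentrates the plateau's power at low frequencies, which is exactly
the signature the spectral-entropy detector responds to.  Had the in-delay
noise been modeled as small-amplitude white noise, its spectrum would be
flat and — because spectral entropy is amplitude-invariant — every delay
frame would score SE ≈ 0.93, silently disabling the SE method while leaving
the MSD and CNN methods intact.

The spacer excursions serve a second purpose: they pin each event's min–max
range near the full 200–700 pA acquisition band, so the normalized-unit
threshold σ < 0.003 corresponds to a stable ~1.5 pA raw-unit criterion
across events.  Without a range anchor, per-event normalization would make
the same rule threshold drift with the realized step spread.

A parameterized contaminant ("noisy delay", default off) adds zero-mean
broadband bursts (10 pA SD, 4–12 ms) inside the delay segment while keeping
its mean level.  These events are still delays — and remain visually
recognizable as such — but their bin SDs exceed the MSD threshold, which is
the documented false-negative mode of the MSD rule that the CNN tolerates.

Default parameters (all overridable via `SimConfig`): event length
1500–4000 samples; block length 150–400 samples; block-level spread 15 pA
around a 450 pA base; within-block noise 12 pA; delay length fraction
0.17–0.25; clipping to [200, 700] pA.  The delay-length floor of 0.17 is
chosen so that every simulated delay spans at least 11 of 75 bins and can
in principle satisfy the >10-bin run rule; shorter delays would be
undetectable by the shipped rule constants by construction, not by noise.
The delay onset is drawn from [0.70, 0.80] but capped so the whole delay
fits before the second spacer feature.

**What the simulator does not emulate:** pore/polymer physics, basecalling,
sequence-dependent level structure (blocks are i.i.d.), 1/f and line noise,
event-detection artifacts, or multi-probe multiplexing.  Passing tests on
simulator data therefore demonstrate the correctness and internal
consistency of the analysis chain at its published operating points — not
real-data performance, which depends on signal features the simulator does
not model.

## Rule classifiers

**MSD.**  The trace is min–max normalized to [0, 1], partitioned into
`total_bins` = 75 near-equal bins (remainder spread over leading bins), and
the per-bin sample SD computed with the N−1 denominator.  An event is
delayed iff some bin whose start lies at fractional position ≥ 0.7 begins a
run of more than `min_run_bins` = 10 consecutive bins with SD <
`sigma_threshold` = 0.003.  "Begins" means the counted run starts inside
the decision region; a flag (`run_may_straddle`) admits runs that merely
end inside it.  This start-inside semantics is equivalent to enumerating
all (start, length) sub-runs, and makes the call monotone in the threshold:
raising σ can only add delayed calls.  The continuous score is the minimum
regional bin SD (lower = more delayed), which gives the rule method a
proper ROC curve.

**SE.**  Spectrogram frames of 128 samples with 50% overlap, Hamming taper,
per-frame mean removal, positive frequencies retained (N = 64 components).
Frame entropy −Σ p log₂ p / log₂ N lies in [0, 1]; a zero-power frame (an
exactly constant plateau) maps to 0, the flat-signal limit.  An event is
delayed iff any frame centered past 0.7 scores below 0.495.  Events too
short to place one frame past 0.7 raise an indeterminate-event error
rather than defaulting to non-delayed, because short events carry a known
length bias for this method.  The framing parameters are a declared
convention of this package; the 0.495 threshold is the published operating
point and holds up well under the simulator's wander model (regional
white-noise frames score ≈ 0.9, plateau frames ≈ 0.2–0.3, step-edge frames
≈ 0.5–0.7).

## CNN

Events are drawn once on a fixed 240×240 master raster — clipped to
[200, 700] pA, median-recentred to 450 pA ("deviation correction", applied
clip-first so out-of-band samples render identically to their clipped
copies), fixed y-limits at the band edges, x spanning the whole event — and
area-average downsampled to the working resolution (56×56 by default; 28,
70, 84, 112, 140 and 240 are supported for resolution sweeps).  The
median-recentring step is this package's concrete realization of the
pre-processing the assay applies before plotting; it removes per-event
baseline offsets while preserving within-event dynamics.

The classifier is LeNet-like: conv 16@5×5 → ReLU → 2×2 max-pool → conv
32@5×5 → ReLU → 2×2 max-pool → FC 64 → ReLU → FC 2, giving 261 250
parameters at 56×56.  It is implemented directly on NumPy (im2col
convolutions, hand-derived backprop verified against central finite
differences to ~1e-10) and trained with Adam (lr 1e-3, β = 0.9/0.999),
batch size 32, at most 20 epochs, early stopping on validation loss with
patience 5 and restoration of the best epoch.  Kernel geometry, optimizer
and schedule are this package's conventions; the layer widths and pooling
are fixed by the published architecture.  Training images are standardized
by the training-set scalar mean/SD, stored on the model and reused at
inference and Grad-CAM time.  Class coding: 0 = delay, 1 = non-delay; the
ROC score is the class-0 probability.

**Grad-CAM** takes the gradient of the target-class logit with respect to
the last convolutional layer's post-ReLU activation maps, averages it
spatially per channel, forms the rectified weighted sum of maps, bilinearly
upsamples to the input resolution and normalizes the maximum to 1.  An
all-zero gradient field returns an all-zero heatmap with a degenerate flag
rather than dividing by zero.

## Barcode filter

Smith–Waterman local alignment with linear gap penalty (−8 per gapped
position; the published scheme gives a single gap value, so no affine
extension is assumed), match +5, mismatch −4, `N` scored as mismatch.
Traceback is deterministic: first-maximum end cell in scan order, diagonal
moves preferred at ties.  The four filters: ≥ 15 exact matches (gaps and
mismatches excluded); ≤ 3 mismatches (gap positions counted separately, not
as mismatches); alignment anchored at reference position 0 with read bases
G,G,G; ≤ 3 mismatches within reference positions 0–9.  "First 10 bases" is
interpreted on the reference, since the motif rules are phrased from the
barcode's perspective.

## Metrics and dose response

Accuracy, precision, recall, F1 and MCC are computed from exact counts with
the positive class = delayed; zero-denominator ratios return NaN with a
flag, never a silent 0.  MCC uses the standard denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) — the variant with a repeated (TN+FN)
factor that circulates in print does not reproduce the published rule-method
MCC values from their own accuracy/precision/recall, while the standard
form does (the acceptance suite enumerates all integer confusion matrices
consistent with those printed values to show this).  AUC is the midrank
Mann–Whitney statistic, identical to the trapezoidal area under the
empirical ROC.  Radar tables min–max scale each metric across classifiers;
constant columns are flagged undefined rather than mapped to an arbitrary
endpoint.

Dose-response: % delayed per (concentration, replicate) cell is
baseline-corrected by subtracting the same replicate's 0 nM value,
outliers are excluded per concentration when deviating from the median by
more than 3× the raw MAD (no 1.4826 consistency factor; when MAD = 0 only
median-equal values are kept, with a warning — with triplicates and
quantized percentages this fires occasionally and is deliberately
conservative), and replicate means are fit by unweighted nonlinear least
squares to R(C) = Vmax·Cⁿ/(Kⁿ + Cⁿ).  Initialization: Vmax₀ = max
response, K₀ = concentration nearest half-max, n₀ = 1; all parameters
bounded positive.  R² = 1 − SSres/SStot; parameter standard errors from the
covariance diagonal.  A single EC50 parameter (`ke_nM`) is reported.
Replicate summaries use SEM = SD/√n with the N−1 denominator; single
replicates report SEM as NaN.

## Problem sizes used by tests and the acceptance script

The benchmark protocol sizes are the published ones (1000/1000 train,
250/250 validation, 1000/1000 blind at 56×56).  The contamination
comparison runs at 400/100/400 events per class with a 10-epoch cap, and
unit tests use 28×28 renderings with a few hundred events — sizes chosen as
the smallest at which the compared quantities are far from their decision
boundaries (e.g. the measured MSD recall drop under contamination is ≈ 0.46
against a 0.2 criterion, and CNN blind accuracy is ≈ 1.0 against 0.9).
Dose-response tests use 6-concentration cohorts of 150–600 events per cell,
where binomial counting noise on % delayed is 1–3 percentage points.

## Known limitations

* Simulator realism limits are listed above; in particular the SE method's
  real-data behavior depends on noise color, which is modeled only
  coarsely (white background, first-order-smoothed delay wander).
* Training determinism is bit-exact only for a fixed platform/BLAS
  configuration; across platforms, expect metric-level rather than
  bit-level reproducibility.
* `dtw_distance` is the classic full dynamic program (no warping-window
  constraint) and is quadratic; it is intended for delay-localization
  diagnostics on single events, not bulk processing.
* The CNN generalizes only to the event geometry it was trained on (delay
  preceding the late spacer feature); it is not a general anomaly detector.
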