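# poredelay

Classification and quantification of **delayed nanopore translocation
events** — the signal signature by which DNA-barcoded probes report the
presence of a target biomarker (e.g. a microRNA) in nanopore sequencing
measurements.

## The problem

A DNA-barcoded probe translocating an unmodified pore produces a noisy,
stepped ionic-current event ("non-delayed").  When the probe has captured its
target, the probe–target duplex stalls while unzipping and the event acquires
a contiguous **low-variability plateau** at fractional position ≥ 0.7
("delayed").  Counting delayed events across a concentration series turns a
nanopore run into a quantitative assay.  This package implements the three
analysis strategies used for that binary call, the read filter that precedes
them, and the dose-response statistics that follow them:

1. **Moving standard deviation (MSD)** — the min–max-normalized trace is
   split into 75 bins; an event is delayed iff more than 10 consecutive bins
   after fractional position 0.7 have sample SD below σ = 0.003
   (`poredelay.rules.classify_msd`).
2. **Instantaneous spectral entropy (SE)** — per-spectrogram-frame normalized
   Shannon entropy of the power spectrum,
   SE(t) = −Σₘ P(t,m) log₂ P(t,m) / log₂ N ∈ [0, 1]; an event is delayed iff
   any frame past 0.7 drops below 0.495 (`poredelay.rules.classify_se`).
3. **CNN** — events rendered to grayscale trace images (240×240 master
   raster, downsampled to 56×56) and classified by a LeNet-style network
   (conv16-ReLU-pool, conv32-ReLU-pool, FC64, FC2), implemented directly on
   NumPy with hand-derived backprop, plus Grad-CAM saliency
   (`poredelay.cnn`).

Around the classifiers: Smith–Waterman alignment of basecalled reads to the
38-nt reference barcode with a four-rule filter (match +5 / mismatch −4 /
gap −8; ≥15 matches, ≤3 mismatches, GGG-anchored start, ≤3 mismatches in the
first 10 bases — `poredelay.barcode`); confusion-matrix metrics, ROC AUC and
radar scaling (`poredelay.stats`); and Hill-equation dose-response fitting
R(C) = Vmax·Cⁿ/(Kⁿ + Cⁿ) with per-replicate baseline correction and MAD
outlier exclusion.

No raw nanopore data are bundled; a synthetic event simulator
(`poredelay.sim`) generates the two signal classes, a parameterized
"noisy-delay" contaminant, concentration cohorts with Hill-distributed
delayed fractions, and barcode-bearing reads.  See `docs/methods.md` for what
the simulator does and does not emulate.

## Worked example

```bash
python examples/02_rule_classifiers.py
```

```
MSD: recall 0.933, false positives 0/60
SE: recall 0.983, false positives 0/60

MSD threshold sweep (dynamic range = % delayed at 100 nM - at 0 nM):
  sigma < 0.001  ->  dynamic range   3.3%
  sigma < 0.002  ->  dynamic range  70.0%
  sigma < 0.003  ->  dynamic range  93.3%
  sigma < 0.004  ->  dynamic range  98.3%
  sigma < 0.005  ->  dynamic range 100.0%
```

Both rules catch most simulated delays without false positives, and the
dynamic-range sweep — the separation between a blank and a saturating cohort
— plateaus around the shipped σ = 0.003 operating point, which is how the
threshold is chosen in practice.  The other examples cover simulation
(`01`), CNN training with Grad-CAM (`03`, prints per-epoch accuracy and the
saliency mass landing in the delay region), barcode filtering (`04`, pass
rate decaying from 1.000 at zero read error to 0.423 at 10% per-base error),
and dose-response fitting (`05`, recovering Ke ≈ 1.2–1.7 nM from a cohort
generated at Ke = 1.19 nM).

A thin CLI mirrors the library for shell use:

```bash
poredelay simulate --out events.jsonl --n-delayed 100 --n-nondelayed 100 --seed 1
poredelay classify events.jsonl --method msd --out calls.tsv
poredelay benchmark --outdir runs/bench --seed 1
```

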