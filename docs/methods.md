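# Methods

This document records the model behind `ecgnoise`, the fixed numerical
choices, and the design decisions that were left open by the problem
statement and resolved here.

## 1. Problem model

A long-term ECG recording is a single-lead, uniformly sampled signal
(default 200 Hz) with continuous annotations assigning every instant one of
five clinical noise types:

- **T0** noise-free;
- **T1** low noise: all subwaves (P, QRS, T) readable despite artifacts;
- **T2** moderate noise: only QRS complexes reliably readable, in at least 3
  consecutive beats;
- **T3** hard noise: QRS hardly or not recognizable;
- **T4** other noise: flatline, calibration pulses, saturation.

Binary mapping for classification: T0, T1 → *clean*; T2, T3 → *noisy*;
T4 → *excluded* (carries no physiological signal). The positive class is
*clean* throughout: a true positive is a clean block classified clean.

## 2. Segmentation

Annotated intervals are cut left-to-right into non-overlapping blocks of
`t_b = 5 s` with a `gap = 1 s` between consecutive blocks (independence
between instances). An interval of duration `d` yields
`floor((d + gap) / (t_b + gap))` blocks; no block crosses an annotation
boundary. Admissible block lengths are 3–6 s.

**Patient filter.** Patients whose clean or noisy share is below 25% of
their instances are discarded from model design: a leave-one-patient-out
test fold with almost no minority class cannot be scored meaningfully. On
the synthetic default cohort this retains 6 of 10 patients, mirroring the
original study cohort.

## 3. Signal conditioning

Per block, in order:

1. **Baseline removal.** Knots at the medians of consecutive non-overlapped
   1.2-s windows; a natural cubic spline through the knots (clamped to the
   knot range at the edges) estimates the wander, which is subtracted.
   Fewer than 4 knots fall back to a linear fit; fewer than 2 windows is an
   error.
2. **Powerline notch.** IIR notch at 50 Hz, quality factor 30, applied
   forward-backward (`filtfilt`, zero phase — offline processing).
3. **Band-pass 0.5–40 Hz.** Cascaded 5th-order Butterworth high-pass and
   low-pass in second-order sections, `sosfiltfilt`.
4. **Normalization.** Per-block z-score with the population standard
   deviation. A zero-variance (flatline) block raises
   `DegenerateBlockError` and is flagged degenerate.

The chain through step 3 is linear: scaling the input by `a` scales the
filtered output by `a` (verified to 1e-6 relative).

## 4. Features (x1–x16)

Computed per 5-s block. Unless noted, inputs are the filtered
(unnormalized) signal; detectors run on the normalized signal.

| # | Feature | Definition |
|---|---------|------------|
| x1 | R-detection agreement | two independent R detectors (derivative-energy Pan–Tompkins style; amplitude peak-picking), greedy matching within 150 ms; matched / max(count) |
| x2 | periodicity ρ | normalized inner product of the block with its circular shift by the median RR (fallback 60/70 bpm): `ρ = s·s̃ / (‖s‖‖s̃‖)` |
| x3 | baseline wander | RMS of the estimated baseline / RMS of the raw block |
| x4 | HF noise | RMS of the >20 Hz residual outside QRS windows, relative to mean R amplitude |
| x5, x6 | mean, SD | population moments of the filtered block |
| x7, x8 | skewness, kurtosis | Fisher–Pearson skew; Pearson kurtosis (Gaussian ≈ 3) |
| x9 | QRS relative SD | SD inside QRS windows / SD of block |
| x10 | spectral purity index | `w2² / (w0·w4)` from trapezoid spectral moments of the Welch PSD |
| x11 | sample entropy | m = 2, r = 0.2·σ, Chebyshev distance; `B = 0 → 0`, `A = 0 → ln B` |
| x12 | relative BW power | power below 1 Hz of the *pre-correction* signal / total |
| x13 | relative QRS power | 5–15 Hz power / 5–40 Hz power |
| x14 | relative QRS energy | energy inside R ± 60 ms windows / total energy |
| x15 | spectral centroid | `∫ f·P df / ∫ P df` over the Welch PSD |
| x16 | MS-QI | modulation-spectrum power at the heart-rate fundamental + 3 harmonics (± 0.3125 Hz) relative to the rest up to 8 Hz, from 250-ms spectrogram envelopes |

Welch PSDs use 1-s Hann windows at 50% overlap; integrals use the composite
trapezoid rule. With no detected R peaks, the QRS-window features fall back
to worst-case values (x4 = 1, x9 = 1, x14 = 0) and the RR-dependent
features use the 70-bpm fallback. Scale invariance holds for x2, x7, x8,
x10, x12, x13, x14, x15 (and x11 through the σ-proportional tolerance);
x5, x6 scale linearly.

## 5. Classification and validation

Feature vectors are standardized with the mean/SD of the *training*
portion only (never the held-out patient). Five families are supported with
their tunable hyperparameters:

| Family | Hyperparameters |
|--------|-----------------|
| `knn` | `k` neighbors (1–51) |
| `dtree` | `msl` min samples per leaf (1–100) |
| `linear_svm` | kernel scale `s` (0.1–150, log), box constraint `c` (0.1–50, log) |
| `slp` | `neurons` (grid 5–100 step 5), optional `l2` |
| `rforest` | `msl` (1–60), `nfeats` (1–16), `ntrees` (50–250) |

**Leave-one-patient-out rotation.** For each patient: all their instances
form the test set; the remaining instances are shuffled and split 80/20
into train/validation (5-fold CV folds available inside train).
Hyperparameters maximize validation F1 — continuous spaces via Bayesian
optimization (expected improvement on a Matérn-2.5 Gaussian-process
surrogate), the perceptron's neuron grid exhaustively. The final model is
refit on train+validation and scored on the held-out patient. Aggregate
performance is the mean ± population SD over patients.

**Metrics.** Acc, Re, Pr, F1, MCC, and nMCC = (MCC+1)/2, positive class
clean. Zero-denominator conventions: Re/Pr/F1 → 0; MCC → 0 when any
marginal is zero.

**Permutation feature importance.** Drop in a fitted model's score when one
feature column is shuffled (10 repeats by default), evaluated on each
rotation's validation set; features can then be ranked and the rotation
repeated with the top-k subset.

## 6. Sliding-window tracking

A trained model slides over a whole recording with a 5-s window and 4-s
overlap (1-s hop): `floor((duration − window)/hop) + 1` windows. Each
window is conditioned, featurized, scaled with the training scaler, and
classified; flatline windows are labelled noisy and flagged degenerate.
Ground truth per window is the majority noise type by duration; exact
clean/noisy ties break toward noisy (conservative for clinical use).
Windows straddling an annotation boundary are scored but also listed in a
transition report, since their label is ambiguous by construction; windows
whose majority is T4 are excluded from scoring.

## 7. Synthetic data

The annotated clinical database is private; `ecgnoise.synth` emulates its
*shape*, not its waveforms:

- **Clean ECG**: per-beat sums of Gaussian kernels for P, Q, R, S, T at
  patient-specific amplitudes and heart rate (55–95 bpm across the default
  cohort), with RR jitter; first beat at RR/2.
- **T1**: mild baseline wander + powerline + broadband noise — subwaves
  remain readable.
- **T2**: EMG-band (20–90 Hz) noise at an RMS that masks P/T waves but
  leaves ≥3 consecutive QRS detectable.
- **T3**: motion transients plus heavy broadband noise — beat train
  destroyed.
- **T4**: flatline (probability 0.5) or square calibration-pulse train.
- **Cohort**: 10 patients, 200 Hz, recordings of 30–300 s tiled from
  scripted segments; 6 patients get a balanced class mix, 2 a clean-skewed
  and 2 a noisy-skewed mix so the 25% filter retains exactly the balanced 6.

**What the generator does *not* emulate:** real inter-patient morphology
variability, arrhythmias, electrode-artifact structure, or the hard
class-boundary cases that make the clinical problem difficult. The
synthetic classes are considerably more separable than real data — rotation
F1 on generator defaults is ≈ 1.0, whereas the original study reports mean
test accuracy 0.75 and recall 0.78. Synthetic results validate the
*pipeline mechanics* (segmentation, leakage-free validation, tracking), not
clinical performance.

## 8. Reference study figures

`ecgnoise.study` stores the published summary figures of the original
(private) cohort: 6748 5-s instances (57.31% clean; T0 2236, T1 1631,
T2 2204, T3 677), the six retained patients, and the tuned perceptron's
per-held-out-patient confusion matrices. Recomputing metrics from those
counts reproduces every published per-patient value at 2 decimals, and the
means 0.75 (Acc) / 0.78 (Re). Note the published aggregate F1 of 0.77 is
the mean of *rounded* per-patient values; the unrounded mean is 0.764.

## 9. Open design decisions resolved here

- **Moments before normalization.** x5/x6 would be identically 0/1 on the
  normalized block, so the statistical features use the filtered,
  unnormalized signal.
- **Gap between blocks** fixed at 1 s.
- **Tie-breaking** in windowed ground truth: toward noisy.
- **Zero denominators** in metrics: fall back to 0 (nMCC to 0.5).
- **Rounding**: reported values round half away from zero to 2 decimals.
- **Boundary-window scoring**: majority-by-duration; how the original
  study scored such windows is unstated.
- **Degenerate windows** (flatline) in tracking: noisy + flagged, since a
  signal-free stretch is clinically unusable but carries no waveform.
- **Seeds**: every derived seed is reduced modulo 2³¹ so downstream
  libraries accept it.
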