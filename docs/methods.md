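# Methods

This note records the scientific and numerical choices behind
`neuroexpertise`: what the synthetic cohort emulates, how each pipeline
stage is defined, which parameters matter, and what the tests do and do
not establish about real recordings.

## 1. Synthetic cohort generator

The generator (`synthdata`) emulates a study design of 30 participants
(10 novices, 9 intermediates, 11 experts) each watching 15 gameplay
videos: 450 trials, each pairing a raw two-wavelength fNIRS recording of
16 prefrontal channels (8 left, 8 right) with an 18-frame × 7-emotion
probability track. Trial durations are truncated-normal
(30.26 ± 14.33 s, minimum 5 s).

**Haemodynamic forward model.** Per trial, an oxyHb time course is built
as a double-gamma HRF (peak 6 s, undershoot 16 s) convolved with a boxcar
from stimulus onset (2 s) to trial end, plus 1/f-shaped Gaussian noise
(SD 0.25 µM). The deoxyHb course is the inverted, 0.3× attenuated copy
with weaker noise. Class structure enters in exactly two ways, both
scaled by `effect_size`:

* amplitude: A(class) = 0.8 µM + `effect_size` · 0.25 µM · (k − 1),
  k ∈ {0, 1, 2} for NV/IT/EX — `effect_size` is therefore the
  between-adjacent-class separation in noise-SD units;
* left/right asymmetry: ±8 % per class step per unit `effect_size`.

Concentrations are pushed through the modified Beer–Lambert law
(extinction coefficients 0.390/1.102 and 1.058/0.691 cm⁻¹ mM⁻¹ at
730/850 nm; d = 2.5 cm; DPF = 6.0) to per-wavelength optical densities,
then to detector intensities around a per-channel baseline level
(U(800, 1200) ADC units), with 0.2 % multiplicative shot noise, clipped
at the 4095 ADC ceiling. Sampling rate is 2 Hz, typical for
continuous-wave prefrontal devices of this class; all optics constants
are configurable.

**Channel failures.** With probability `channel_fail_rate` (default
0.12) a channel-trial is corrupted into exactly one failure mode, chosen
uniformly: near-zero signal (×10⁻³), saturation clamp (×8, clipped at
the ceiling), or light leakage (multiplicative noise with CV ≈ 0.4).
One mode per corrupted channel keeps QC reasons testable.

**Emotion tracks.** 18 rows drawn from a Dirichlet with concentration
3·**1**₇, plus a class-preferred component (novice → Neutral,
intermediate → Surprise, expert → Happiness) of weight
2 · `emotion_effect_size`. `emotion_effect_size` defaults to
`effect_size` but can be set independently, which is how an
"emotion-only" cohort (brain at chance, fusion informative) is
constructed for testing the fusion pathway.

**What the generator deliberately omits.** Trials are independent given
the class label: there are **no participant-level random effects**. Real
cohorts have strong participant signatures; with class-only stratified
CV those signatures allow participant memorisation and above-chance
accuracy even with no true class effect. Omitting them makes the null
generator genuinely chance-level — the property the calibration tests
rely on — at the cost of realism. Consequently, passing tests show the
pipeline recovers class structure *of the modelled kind*; they do not
certify accuracy levels on real recordings, where participant identity,
session drift and motion artifacts intervene. Head motion, Mayer waves
and systemic physiology are likewise not modelled (the 0.14 Hz low-pass
would remove most of them anyway).

## 2. Preprocessing

Order: channel QC → per-wavelength zero-phase low-pass → Beer–Lambert
against the pre-onset baseline → 3-SD outlier removal → resampling to a
fixed 60-sample grid. Whether filtering preceded optical-density
conversion in the original protocol is ambiguous; filtering intensities
first is declared here (a linear zero-phase filter before a logarithm of
slowly varying signals makes little practical difference at these noise
levels).

* **QC** (first matching rule wins): *saturated* if ≥ 1 % of samples sit
  at/above 4095; *low signal* if the median intensity < 20 units;
  *light leakage* if the within-channel CV > 0.10. Clean forward-model
  channels have CV ≈ 2–3 %, corrupted ones ≈ 40 %, so the thresholds
  separate the modes with wide margins; all three live in config.
* **Low-pass**: 4th-order Butterworth, 0.14 Hz cutoff, applied
  forward–backward (zero phase, DC gain exactly 1). Padding length is
  capped for very short trials.
* **Outliers**: single-pass mean/SD of each haemoglobin series; samples
  beyond 3 SD are replaced by linear interpolation from retained
  neighbours so the fixed-length grid survives (deletion would not).
  Zero-variance series pass through unchanged. On Gaussian noise this
  removes 2Φ(−3) ≈ 0.27 % of samples.
* **Grid**: linear resampling to L = 60 samples (30 s × 2 Hz). The
  kernel transform and the deep models need fixed dimensionality and
  trial durations vary threefold; resampling to the mean duration keeps
  waveform shape while standardising length.
* Failed channels stay in the arrays, flagged by the quality mask. They
  are excluded from the {All, Left, Right} aggregates and, before the
  kernel transform (which needs all 16 rows), mean-imputed from the
  passed channels of the same hemisphere.

## 3. Features

* **Statistical battery** (per series): mean, sample SD, max, min,
  range, OLS slope vs sample index, Fisher skewness (0 for constant
  input), and zero-crossings of the mean-centred series ignoring exact
  zeros. Applied to the three passed-channel aggregates → 450 × 24; the
  fused variant adds the battery on each of the 7 emotion series
  → 450 × 80. (A config flag instead flattens the raw 18×7 scores.)
  Per-channel features exist behind a flag but are not part of the
  default matrix.
* **Kernel transform**: 100 kernels per series family, (max, PPV)
  pooling → 3200 columns (brain) / 4600 (fused). The emotion series live
  on an 18-sample grid, so they get their own kernel bank (same seed
  stream); a single bank could not satisfy the span constraint for both
  lengths.
* No feature normalisation precedes the classical models; the deep
  models standardise per feature with training-fold statistics only
  (the 10⁻⁵-scale learning rates are only sensible on standardised
  inputs).

## 4. Classifiers

Classical models run at fixed reference settings: RF (30 trees, depth
≤ 10), SVM (RBF, gamma = auto), kNN (k = 3), GNB (defaults), XGB
(multiclass softmax, colsample 0.3, lr 0.1, depth 3, α 5, 15 rounds).

FCDNN and DCAE are NumPy implementations with explicit backprop
(verified against finite differences to 10⁻⁴ relative) and Adam
(β₁ = 0.9, β₂ = 0.999 assumed; only the learning rates are prescribed).
Architectures and per-variant optima (block widths, dropout rates,
learning rates, 1000 epochs) are frozen as defaults in
`models/deep.py`. Design points worth flagging:

* The DCAE classifier head ends in a tanh **before** the cross-entropy;
  the tanh outputs are treated as softmax logits. This bounds the logits
  to [−1, 1] (capping per-example confidence) but preserves argmax; a
  `final_tanh=False` flag removes it.
* Training is full-batch by default (a few hundred trials); a
  `batch_size` parameter enables minibatching, which multiplies the
  number of Adam steps per epoch and is what the reduced-epoch test
  configurations use.
* Weight init is seeded He-style; dropout is inverted and active only
  during training, so fitted predictions are deterministic.
* The plateau rule stops a trial when the total loss falls by less than
  10⁻⁵ per 100 epochs (a flat loss stops exactly at epoch 100). It is
  active inside hyperparameter search and optional elsewhere.
* Hyperparameter search is a compact in-package tree-structured Parzen
  estimator (`models/tpe.py`): random start-up, γ = 0.25 good/bad split,
  per-dimension Parzen densities (log-space for learning rates),
  candidates scored by the good/bad density ratio. It is off in
  reproduction runs — the frozen optima are the defaults.

## 5. Evaluation and hypothesis battery

10× repeated stratified 5-fold CV; each fold's held-out 20 % is the test
set (the "20 % test" reading adopted: a fold *is* the test split).
Stratification is by class only; a `group_by_participant` option keeps
each participant's trials on one side of every split, which matters on
data with participant effects. Metrics are macro-averaged percentages
(macro chosen for the near-balanced 3-class design; weighted averaging
available). Per-class precision for a never-predicted class is 0, with a
warning.

* **H01/H02**: Kruskal–Wallis on the two F1 samples (n = 50 each),
  α = 0.05, with a median-direction gate realising the one-sided claim
  (KW itself is omnibus). Degenerate all-equal samples give p = 1.
* **H03**: all records ranked jointly; pairwise mean-rank differences
  reported with confidence bounds at the Šidák-adjusted level
  1 − (1−α)^(1/m) over the m = 21 pairs; a pair is significant iff its
  interval excludes 0, equivalently iff its Šidák-adjusted p < α.
* The 50 CV records are treated as independent samples, as the
  n = 50-per-group tests imply. They are not strictly independent
  (folds of one repeat share training data), so the battery's effective
  α is approximate; this caveat is inherited by design.
* Two baselines: zero-rule (majority class) — the reference for the H01
  *power* checks — and stratified-random. For **type-I calibration** the
  stratified-random baseline is the valid reference: under macro-F1 the
  zero-rule baseline scores ≈ 16.7 % on balanced classes while any
  chance-level classifier scores ≈ 33 %, so "no difference from
  zero-rule" is false even under the null generator. Against the
  stratified-random baseline the measured H01 rejection rate under the
  null is ≈ 5 % at α = 0.05.

## 6. Problem sizes used by the test and acceptance runs

The full protocol (450 trials, 100 kernels, 1000 epochs, 10×5 CV) is the
configuration default. The automated checks run the same code at sizes
chosen to keep the whole suite in the minutes range while leaving every
conclusion intact:

* structural checks: the full 450-trial cohort and full feature widths;
* null calibration: 450 trials, classical models on the 24-column
  statistical matrix with 2×5 CV; deep models on a 20-kernel (640-column)
  matrix, 20 epochs, 1×5 CV — under the null, training length does not
  move accuracy off chance;
* H01 type-I: 200 Monte-Carlo replicates of 90-trial null cohorts,
  2×5 CV;
* effect recovery: 135 trials at `effect_size = 3`, 20 kernels, DCAE
  100 epochs / FCDNN 200 epochs with minibatch 32 (more optimiser steps
  per epoch compensating the shorter schedule), 1×5 CV;
* emotion-only fusion: 135 trials, brain effect 0, emotion effect 2,
  statistical features, three classical models.

## 7. Known limitations

* No participant-level heterogeneity, motion artifacts or systemic
  physiology in the generator (see §1); accuracy numbers on synthetic
  cohorts are not forecasts for real data.
* The tanh-before-cross-entropy head is faithful to the reference
  architecture but unusual; with it, per-class logits saturate and very
  confident posteriors are unreachable.
* The Dunn–Šidák bounds use the large-sample normal approximation for
  rank-mean differences; at n = 50 per group this is standard but
  approximate under heavy ties.
* QC thresholds are calibrated to the generator's failure modes; real
  devices need device-specific values (all are config fields).
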