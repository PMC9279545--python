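# Methods

This note records the modelling and numerical choices behind the package,
their defaults, and what the synthetic experiments do and do not show.

## Led-Pattern (S-box textural descriptor)

The descriptor turns a 1-D signal of length L into 512 histogram features.
A 16-sample window slides with stride 1 (L − 15 windows). Within a window
v₁…v₁₆, bit k is the two-argument signum comparison
`bit(k) = 1 iff v_k − v_{S[k]} ≥ 0`, where S is the LED block cipher's
4-bit S-box `[12, 5, 6, 11, 9, 0, 10, 13, 3, 14, 15, 8, 4, 7, 1, 2]`
(identical to the PRESENT S-box) read 0-based: position k is compared with
position S[k]. Bits 1–8 and 9–16 are packed into a left and right byte,
earliest bit least significant; the two byte streams are histogrammed into
256 bins each and concatenated left-then-right.

Conventions worth stating:

* **Ties.** A zero difference takes the 1 branch, so a constant window
  encodes (255, 255). This makes the descriptor exactly invariant to
  adding a constant and to positive rescaling (the signum depends only on
  difference signs).
* The histogram bin of a code is the code itself (0–255).
* Signals shorter than 16 samples are rejected with the minimum named.

## Statistical moment vector

Fourteen components in fixed order: mean, sample SD (ddof = 1), sum,
entropy-like statistic, mean absolute first difference (sum of the M − 1
|Δ| divided by M), bias-corrected skewness and excess kurtosis, median,
min, max, energy Σx², RMS, range, max − mean.

* **Entropy-like statistic.** Defined as −Σ p·ln p with p_i = x_i / RMS,
  summed over the samples with p_i > 0 only; the logarithm is undefined
  for non-positive ratios, and zero-filling keeps the statistic total.
  A zero-RMS (all-zero) signal maps to 0. This is the largest
  interpretive choice in the module; it is isolated in one helper so an
  alternative reading (absolute values, squared ratios) can be swapped in.
* **Median.** Element ⌈M/2⌉ (1-based) of the ascending-sorted signal — the
  lower-middle element for even M, with no interpolation. This differs
  deliberately from the conventional even-length median.
* **Skewness/kurtosis.** The bias-corrected sample forms
  (`skewness(x, 0)` / `kurtosis(x, 0)` in common statistical toolboxes;
  kurtosis is reported as excess). Zero-variance signals return 0 for both
  rather than dividing by zero.
* Minimum length 4 (the kurtosis correction needs M > 3).

## TQWT

The tunable Q-factor wavelet transform is implemented as the radix-2
DFT-domain oversampled two-channel filter bank: β = 2/(Q+1),
α = 1 − β/r, with α + β > 1. Each level keeps ~αN low-pass and
~βα^(j−1)N high-pass DFT samples (rounded to even against the *original*
length, so synthesis can recompute every size exactly), with
Daubechies-style transition bands θ(ω) = ½(1+cos ω)√(2−cos ω), which are
power complementary (θ(ω)² + θ(π−ω)² = 1) and give perfect
reconstruction; the unitary DFT normalization additionally makes total
sub-band energy equal signal energy exactly. Measured round-trip error is
at machine precision (~1e-15 relative), far inside the 1e-8 tolerance the
tests assert.

* Band order: details finest (level 1) to coarsest, then the final
  low-pass band — J + 1 bands; 18 at the pipeline default (2, 3, 17).
* Odd-length signals are zero-padded by one sample; the pad is recorded
  and stripped on reconstruction.
* `max_levels` bounds the depth by requiring the coarsest band to keep at
  least 8 samples: floor(log(βN/8)/log(1/α)). Note the *feature pipeline*
  needs every band to reach 16 samples (the textural window), which in
  practice requires frames of roughly ≥ 1200 samples at (2, 3, 17); the
  default 7650-sample frame leaves a comfortable margin.

## Fusion

Per signal: positions 0–511 the textural histograms, 512–525 the moments
of the signal, 526–539 the moments of the 512 textural counts. Per frame:
block 1 is the raw frame, block h + 1 is sub-band h, giving 19 blocks of
540 = 10,260 features, with per-column provenance
(`s{signal}_{kind}_{index}`) carried alongside the matrix and persisted as
a CSV sidecar. Framing discards trailing samples that do not fill a whole
frame (38,252 samples → 5 frames of 7650, 2 discarded). Channels never
mix: each channel is an independent pipeline, matching how channel-wise
EEG emotion results are reported.

## RFIChi2 selection

* **ReliefF**: k = 10 nearest hits/misses (all observations used, uniform
  neighbor weighting), Manhattan distance on features min-max scaled to
  [0, 1]; miss contributions weighted by P(class)/(1 − P(own class));
  constant features get weight 0. Classes with fewer than k available
  neighbors use all they have.
* **Pruning**: strictly negative weights are removed (the method's
  automatic redundancy cut); zero-weight features survive.
* **Chi-square ranking**: 10 equal-width bins over each feature's observed
  range; the Pearson statistic of the bin × class table, empty bins
  dropping out; ties broken by original column index. The discretization
  is isolated behind one function since any binning choice is defensible.
* **Iterative sweep**: candidate sizes 100…1000 step 1 (901 candidates),
  each scored by the cubic SVM's misclassification under one seeded
  stratified 10-fold partition shared across all sizes so the curve is
  comparable; minimum loss wins, ties to the smallest size. The range is
  clipped (with a warning) when fewer features survive pruning.
  Implementation note: because the ranked top-s sets are nested, the
  sweep maintains the training/test inner-product matrices by rank-1
  updates per feature and evaluates the polynomial kernel from them, so
  the 901 evaluations cost one SVM fit each rather than one Gram-matrix
  recomputation each. The selection partition and the final evaluation
  partition use independently derived seeds.

## Cubic SVM and metrics

Degree-3 polynomial kernel K(x, y) = (γ·⟨x, y⟩ + 1)³, one-vs-one
multi-class coding, box constraint C = 1. Features are standardized with
training-fold statistics only. The "automatic" kernel scale is the median
pairwise Euclidean distance over a seeded subsample of at most 256
standardized training rows, γ = 1/scale² (unit scale if the subsample is
degenerate). Out-of-fold predictions from a stratified seeded 10-fold CV
form one confusion matrix; accuracy = trace/total, AR/AP are macro
averages, F1 is the harmonic mean of AP and AR (exactly, by
construction), and the geometric mean of per-class recalls is reported as
a separate, imbalance-sensitive summary. A never-predicted class
contributes a zero precision term. For balanced classes accuracy equals
AR identically. A single seeded CV run is performed (no repetition); the
seed is part of every report.

## Synthetic corpus

`SyntheticSpec` defaults: 28 subjects, 14 channels (EMOTIV EPOC montage),
128 Hz, recordings of 38,252 samples framed at 7650 (5 frames each),
4 classes. Each subject × class × channel recording is a sum of 3
random-frequency, random-phase sinusoids per classical EEG band
(delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz) with
per-band power following a class-specific profile, plus AR(1) noise
(sd 1.0, coefficient 0.9 — a crude 1/f-ish floor). The four default
profiles differ mainly in the alpha/beta/gamma balance, loosely evoking
calm-vs-arousing conditions. Generation is a pure function of the seed;
requesting a channel subset consumes the full montage's draws so the
subset matches the full corpus sample for sample.

What this does *not* emulate: volume conduction / channel correlation,
nonstationarity, artifacts, subject variability beyond fresh random
draws, and realistic class overlap. End-to-end accuracy on this corpus is
a pipeline sanity check (the classes are spectrally well separated by
construction), not evidence about real EEG performance; the permuted-label
control verifies the other direction, that the pipeline finds nothing
when there is nothing.

Dataset readers: GAMEEMO-style CSVs (both the all-channels-per-file and
one-file-per-channel layouts; class from the G1–G4 token, mapped
G1 boring, G2 calm, G3 horror, G4 funny) and DREAMER-style MAT containers
(per-trial 14-channel EEG; arousal/dominance/valence ratings binarized
against a caller-supplied threshold — deliberately a required argument,
since no canonical cutoff exists; "valance" is accepted as a spelling).
DREAMER-style trials keep their native variable lengths (every extractor
is length-agnostic); only long GAMEEMO-style recordings are framed. The
writer halves of both readers exist so reader tests run offline on
synthetic stand-ins.

## Problem sizes used in the checks

The test suite and the acceptance script run the planted-recovery
experiment at 200 observations × 2050 features (50 informative), and the
end-to-end experiment on one representative channel (AF3) of the default
28-subject corpus — 560 frames × 10,260 features; each channel is an
identical, independently seeded pipeline, so one channel exercises every
code path. Oracle-agreement checks use 100+ random signals each.

## Known limitations

* The chi-square sweep's loss is computed on the same data used to pick
  the size (standard for this selector family); the final reported
  accuracy uses an independent fold partition but not a held-out subject
  split, so subject-level generalization is out of scope.
* ReliefF is O(n²·features) via a full distance pass; fine at the corpus
  sizes here, but large studies would want approximate neighbors.
* The entropy-like moment and the chi-square binning are single-function
  interpretation points (see above) rather than settled definitions.
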