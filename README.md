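# ledpatnet

Channel-wise EEG emotion recognition with a cipher-S-box textural
descriptor, multilevel wavelet feature fusion, hybrid feature selection and
a cubic-kernel SVM.

The package is aimed at researchers in affective computing / biomedical
signal processing who want a fully reproducible, dependency-light
implementation of a hand-crafted (non-deep) EEG classification pipeline
that can be exercised end to end on synthetic signals, and applied to
GAMEEMO-style CSV or DREAMER-style MAT corpora when those are available.

## The method

For each EEG channel independently:

1. **Framing.** A long recording is cut into non-overlapping segments of
   7650 samples (≈ one minute at 128 Hz).
2. **Decomposition.** The tunable Q-factor wavelet transform (TQWT) with
   Q = 2, r = 3, J = 17 decomposes each frame into 18 sub-bands
   (17 detail bands, finest first, plus the final low-pass band).
3. **Fused feature extraction.** Each of the 19 signals (raw frame + 18
   sub-bands) yields 540 features:
   * 512 **Led-Pattern** features: a 16-sample window slides over the
     signal; inside each window, position *k* is compared with the position
     the LED cipher's 4-bit S-box maps *k* to, `bit(k) = 1` iff
     `v_k − v_{S[k]} ≥ 0`; the first and last 8 bits form a left and a
     right byte, and the two byte streams are histogrammed into 256 bins
     each;
   * 14 statistical moments of the signal (mean, sample SD, sum, an
     entropy-like statistic, mean |Δ|, corrected skewness and kurtosis,
     lower-middle median, min, max, energy, RMS, range, max − mean);
   * the same 14 moments of the 512 textural features.

   Concatenation gives the 19 × 540 = **10,260**-feature vector per frame.
4. **RFIChi2 selection.** ReliefF weights every feature; negative-weight
   features are pruned; survivors are ranked by a binned chi-square
   statistic against the label; every candidate size s ∈ [100, 1000]
   (901 candidates) is scored by the cubic SVM's ten-fold cross-validated
   misclassification rate on one shared seeded partition; the
   loss-minimizing s wins (ties → smallest).
5. **Classification.** A degree-3 polynomial-kernel SVM (one-vs-one,
   C = 1, automatic kernel scale) under stratified ten-fold CV produces a
   confusion matrix and the metric set: accuracy, macro average recall AR,
   macro average precision AP, F1 = 2·AP·AR/(AP+AR), and the geometric
   mean of per-class recalls.

## Worked example

```python
import numpy as np
from ledpatnet import (
    SyntheticSpec, generate_dataset, feature_matrix_from_frames,
    rfichi2_select, cubic_svm_cv,
)

spec = SyntheticSpec(seed=1)                     # 28 subjects, 4 classes
frames = generate_dataset(spec, channels=("AF3",))["AF3"]
fm = feature_matrix_from_frames(frames)          # 560 frames x 10,260 features
sel = rfichi2_select(fm, seed=7)                 # ReliefF -> Chi2 -> 901-size sweep
report = cubic_svm_cv(fm.select(sel.selected), folds=10, seed=11)
print(fm.X.shape, sel.chosen_size, round(report.accuracy, 4))
```

prints

```
(560, 10260) 100 1.0
```

i.e. 560 one-minute frames carry 10,260 features each; the selector settles
on the 100 best-ranked features (the smallest candidate size, since the
cross-validated loss is already zero there); and the selected features
classify the four synthetic emotion classes perfectly — the synthetic
classes differ strongly in band power, so this is a pipeline sanity check,
not a claim about real EEG.

The same flow is available from the shell:

```sh
ledpatnet simulate --seed 1 --n-subjects 2 --out data/
ledpatnet run --source data/ --channels AF3 --seed 1 --out results/
```

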