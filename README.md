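# gaitrec

Recognition of the basic indoor locomotion activities — **standing**,
**walking**, **ascending stairs**, **descending stairs**, plus a
**messing-around** rejection class — from the accelerometer and
gyroscope of a smartphone carried in a trouser pocket (*pocket-case*)
or held in hand with the display facing the user (*hand-case*).

The package is aimed at activity recognition as a supporting signal for
indoor localisation: classifications must be orientation-independent,
low-latency, cheap enough for a phone, and able to flag windows where
the user is just playing with the device.  It provides three
interchangeable recognition pipelines over 50 Hz dual-sensor streams,
one-class outlier rejection, an evaluation harness, and a synthetic
gait simulator so everything is testable end-to-end without any data
download.

## The methods

All pipelines slide synchronized windows (2–3 s) across the sensor
channels; the set of per-channel sequences at one time point is a
*time-window*.

**Analytical transforms + virtual sensors.**  Each channel's
`w`-sample sequence is treated as a `w`-dimensional vector and reduced
by a per-channel linear transform: PCA (top-`d` eigenvectors of the
pooled covariance, eigenvalues = variances along them) or multiclass
LDA (top-`d` eigenvectors of `S_w^{-1} S_b`).  The per-channel
projections are concatenated — 6 channels × 3 dims = an 18-dim feature
vector, for example.  To give this linear method some non-linear
separation power, *virtual sensors* add 15 artificial channels
computed from the raw streams: acceleration magnitude `sqrt(aᵀa)`,
per-channel standard deviation and RMS over a `w_virt = 15`-sample
sliding window (delay `(w_virt−1)/2` samples), and the inclination
angles `f_TD = atan2(a_y, a_z)`, `f_LR = atan2(a_x, a_z)`.

**Codebook.**  Sequences of `w_seq = (n_sub−1)·s_i + w_sub` samples are
cut into `n_sub` subsequences of `w_sub` samples at stride `s_i`; a
k-means codebook of `|C|` characteristic shapes is learned per sensor,
and each subsequence is soft-assigned to all codewords with Gaussian
weights `∝ exp(−d²/2σ²)`, averaged into per-channel histograms that sum
to 1.  Defaults: `n_sub = 32`, `w_sub = 32`, `s_i = 2` (94 samples ≈
1.88 s), `|C| = 32`, `σ = 0.25`.

**Statistical features.**  A battery per time-window — MFCC over a
geometric-growth (`ψ`) triangular filter-bank, Yule–Walker AR
coefficients, signal magnitude area, variance, 256-bin entropy,
channel correlations, 75th percentile, extrema, gyro integration and
gradient channels — concatenated and compressed by a single analytical
transform (default LDA) before classification.

Classification uses kNN (`k = 3`) or an RBF-kernel SVM; results are
reported as a confusion matrix with **average class accuracy** (mean
per-class recall) and macro F1.  Messing-around windows are rejected
by a one-class RBF SVM trained on locomotion features only, with its
kernel scale `γ` tuned by log-grid search plus local refinement.

## Worked example

```python
from gaitrec import make_benchmark_suite, run_benchmark, AnalyticConfig

suite = make_benchmark_suite(seed=1)          # 8 subjects x 5 activities x 60 s, both carry modes
result = run_benchmark(suite, AnalyticConfig(), seed=0)
for mode in ("pocket", "hand", "combined"):
    print(f"{mode}: {result.accuracy[mode]:.1f}% "
          f"(macro F1 {result.macro_f1[mode]:.1f}%)")
print("outlier stage:", {k: round(v, 1) for k, v in result.outlier.items()})
```

prints

```
pocket: 99.9% (macro F1 99.9%)
hand: 99.3% (macro F1 99.3%)
combined: 99.6% (macro F1 99.6%)
outlier stage: {'positive_accuracy': 95.2, 'outlier_accuracy': 100.0, 'mean_accuracy': 97.6}
```

i.e. on the synthetic benchmark the analytical-transform pipeline
(PCA, `d = 5`, 2 s windows, raw acceleration plus all virtual sensors,
SVM-RBF), trained once on the pooled windows of both carry modes,
classifies 99.6% of held-out locomotion windows correctly on average
per class, while the outlier stage accepts 95.2% of locomotion windows
and flags 100% of messing-around windows.

The same flows are available from the shell:

```sh
gaitrec simulate --mode both --seed 7 --out data/
gaitrec evaluate --data data/ --pipeline analytic
```

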