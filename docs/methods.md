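# Methods

## Sensor model and coordinate conventions

An accelerometer sample in the device frame is modelled as
`a = a_static + a_dynamic + a_noise` with
`a_static = O_{E→L} · (0, g, 0)ᵀ`, `g = 9.81 m/s²`: the earth frame is
chosen with the y-axis up, and its two horizontal axes are left
*underspecified* — they are whatever the orientation filter yields,
because aligning them to an external reference (e.g. magnetic north)
would make features sensitive to walking direction.  The gyroscope
measures angular velocity about the device axes in rad/s,
`θ = θ_dynamic + θ_noise`.

Orientation `O_{E→L}` is estimated by a complementary filter: the
gyroscope is integrated per sample (rotation-vector update) and the
estimate is nudged toward the accelerometer's gravity direction with a
per-sample weight of 0.02 (≈ 1 s time constant at 50 Hz) for long-term
stability.  The filter stage is pluggable — any externally supplied
orientation series can be substituted — and a trailing-mean
pure-accelerometer estimator is included as a slow reference.
Orientation-aligned acceleration can be collapsed to the two-channel
representation `(â_y, sqrt(â_x² + â_z²))`, which is exactly invariant
to rotations about gravity; the price is the loss of tilt information,
which the inclination virtual sensor reintroduces from the raw
signal.

Device bias calibration is out of scope (phone operating systems
handle it); the simulator nevertheless injects small residual biases
so the pipelines are exercised under realistic imperfection.

## Windowing

Windows are half-open, 0-based sample ranges; 2 s at 50 Hz = 100
samples.  The operational window step defaults to a quarter of the
window.  For training, labelled activity segments are extended at both
ends by `floor(w/3)` samples into their neighbours before window
extraction, so activity transitions appear in both adjacent classes;
the extension deliberately stays below `w/2`, which would place
identical windows in two classes.  Extension is applied symmetrically
to both sides of a boundary.  Windows that do not fit are dropped, not
padded.

## Analytical transforms

PCA is computed from the pooled (population) covariance of all
training sequences of a channel, all classes together; the training
mean is the centering reference for embedding as well (windows are not
re-centred per window — per-window centering would discard the mean
level, which carries gravity/tilt information on acceleration
channels).  Eigenvector signs are fixed so each vector's
largest-magnitude component is positive; ties in eigenvalues resolve
by the deterministic ordering of the symmetric eigensolver under fixed
input ordering.

LDA is the multiclass (Rao) variant: generalized eigenvectors of
`S_b v = λ S_w v` with unnormalised scatter matrices.  A
(near-)singular within-class scatter — routine when a class has fewer
sequences than window samples — is ridge-regularised with
`ε = 1e-6 · trace(S_w)/w` and a warning.  The retained dimension is
capped at `n_classes − 1`, the rank of `S_b`; with the four trainable
locomotion classes this means a requested `d = 5` is capped to 3 with
a warning.  Basis rows are unit-normalised for scale stability.

Optional per-channel variance normalisation (pure scaling to unit
pooled variance, no centering) exists to make eigenvalue plots
comparable across channels; it is off by default for classification.

## Virtual sensors

The default set (15 channels on top of the 6 hardware channels):
acceleration magnitude (1), per-channel standard deviation of both
sensors (3+3), per-channel RMS of both sensors (3+3), inclination
(2).  Windowed metrics use `w_virt = 15` samples (0.3 s at 50 Hz), odd
so the attribution delay `(w_virt − 1)/2 = 7` samples is integral;
population (1/N) denominators throughout.  Magnitude defaults to the
Euclidean norm with a flag for the literal squared form `aᵀa` — both
are rotation invariant.  Inclination always consumes raw device-frame
acceleration, even when the pipeline otherwise runs on aligned
acceleration, since tilt is exactly what alignment removes.  Streams
are synchronised by cropping everything to the common time support of
the delayed windowed channels.

## Codebook features

Codewords are k-means centres (k-means++ initialisation, 10 restarts,
fixed seed; the clustering algorithm sits behind `train_codebook` and
can be swapped).  One codebook per sensor is trained on the pooled
subsequences of its three channels; subsequences are *not*
z-normalised before the Euclidean distance — the method's partial
magnitude invariance comes from shape comparison alone, and full
normalisation would discard amplitude cues.  Soft assignment weights
`exp(−d²/2σ²)` are computed after subtracting the row-minimum squared
distance (mathematically neutral, numerically safe); σ → 0 approaches
hard nearest-codeword assignment, σ → ∞ the uniform histogram.
Per-channel histograms are the mean over the `n_sub` subsequence
assignments (summing-then-normalising is identical) and the per-channel
histograms are concatenated for classification.  Streaming
featurisation advances sequences by `n_sub/4` subsequences and reuses
each subsequence's assignment across the four overlapping sequences;
this caching is bit-identical to naive recomputation and is verified
as such.  An `n_sub` not divisible by four falls back to
`floor(n_sub/4)` with a warning.

Defaults: `σ = 0.25`, `|C| = 32`, `w_sub = 32`, `n_sub = 32`,
`s_i = 2`, raw acceleration, channel-independent assignment (the
append-across-channels strategy is implemented and selectable).  The
tuner's default grids are `σ ∈ {0.25, 0.5}`, `|C| ∈ {16, 32, 64}`,
`w_sub ∈ {32, 48, 64, 96}`.

## Statistical features

The MFCC filter-bank is parametrised by the filter count `n_mel` and
growth factor `ψ`: edge frequencies from 0 to Nyquist with gaps
growing geometrically by `ψ`, triangular filters on consecutive edge
triples (50% overlap), optionally area-normalised.  This construction
was an open design point; it is isolated behind `mfcc_filterbank` so a
different tiling can be substituted.  No taper is applied before the
FFT: the sequences are short, the bank is coarse, and an untapered
magnitude spectrum keeps periodic signals shift-tolerant.  Log
energies are floored at `1e-12` and decorrelated with an orthonormal
type-II DCT.

AR coefficients default to Yule–Walker with biased (1/N)
autocovariances; Burg is selectable.  SMA is the standard signal
magnitude area `(1/w) Σ_t Σ_c |x_c[t]|` (the exact formula was another
open point).  Entropy uses a 256-bin equal-width histogram over the
window's own [min, max].  Correlation covers all unordered channel
pairs in lexicographic order, reporting 0 with a warning when a
channel has zero variance.  The 75th percentile interpolates linearly
at rank `0.75·(w−1)`.  "Integration" is the rectangular integral of
each gyro channel over the window; gradient channels are first
differences.  Variance on inclination is per inclination channel (2
dims); no smoothing is applied to the inclination gradient.

Defaults mirror the best-performing configuration: `n_mel = 10`,
`ψ = 1.6`, unnormalised filters, `|q| = 5`, 2.5 s windows, LDA
reduction (requested `d = 5`, capped at 3 by the class count),
two-channel acceleration.  Feature-vector dimension is 126 for raw
acceleration and 108 for the two-channel convention at these
defaults.

## Classification and outlier rejection

kNN uses `k = 3` and plain Euclidean distance on the reduced feature
vectors.  The SVM uses an RBF kernel, one-vs-one multiclass scheme and
default regularisation `C = 1` (no value is prescribed by the method),
with per-feature standardisation inside the classifier pipeline since
the three front-ends produce features on very different scales.
Probability outputs are available but off by default.

Average class accuracy is the unweighted mean of per-class recalls —
invariant to class imbalance — and macro F1 the unweighted mean of
per-class F1; a class absent from both actual and predicted samples is
excluded with a warning, a present class with zero precision and
recall contributes F1 = 0.  Evaluation splits windows 70/30 per class
with a seeded permutation.

The outlier stage trains a one-class RBF SVM (`ν = 0.05`) on positive
locomotion features only.  Its scale γ is found by a deterministic
coarse log-grid search (`10⁻⁴…10³`) with two rounds of local geometric
refinement, maximising the unweighted mean of positive- and
outlier-class validation accuracies — a derivative-free stand-in for
gradient-based tuning that is reproducible by construction.  Reference
starting points per pipeline: 0.005 (analytic), 15.0 (codebook), 4.55
(statistical).

## Synthetic data generator

The simulator produces what the pipelines need to be exercised
honestly, not a biomechanical model.  Per carry mode it fixes a rest
orientation convention (pocket: device y along the thigh; hand: z out
of the display, pitched 40° toward the face) and composes it with the
activity's tilt dynamics `θ(t)` about the device x-axis; measured
acceleration is the rotated gravity-plus-dynamic vector, the gyroscope
the tilt derivative plus aperiodic components, with Gaussian noise
(0.25 m/s², 0.03 rad/s) and small per-channel biases.

Class signatures follow the qualitative observations the recognition
problem rests on: walking is sinusoid-plus-harmonics at the mode's
fundamental (pocket 0.9 Hz leg frequency, hand 1.8 Hz step frequency —
roughly double); stair ascent has longer, higher thigh-raise peaks
(larger inclination integral) at 0.8× cadence; stair descent has
sharper, shorter peaks (sharpness `κ = 8`) with reduced inclination at
1.15× cadence; messing-around is gated heavy-tailed (Student-t, ν = 2)
burst noise.  The benchmark suite simulates 8 subjects × 5 activities
× 60 s per carry mode with per-subject jitter (±20% frequency, ±30%
amplitude, random carry yaw, 5° tilt scatter) and regenerates
bit-identically from its seed.

What the generator does **not** emulate — and hence what passing
end-to-end tests do not show about real data: inter-step timing
variability and gait asymmetry, soft-tissue and pocket-slip artefacts,
sensor-grid jitter and dropped samples, the full diversity of human
messing-around, and any overlap in cadence between people walking and
taking stairs, which is far larger in reality.  The synthetic
accuracies (≈ 96–99%) are accordingly much higher than what the same
pipelines reach on real recordings; they validate the machinery, not
field performance.

## Problem sizes and numerical choices

The shipped benchmark runs at 8 subjects × 5 × 60 s × 2 modes
(2.4 M samples), giving ≈ 1500 training and ≈ 600 test windows per
pipeline per mode; k-means training subsequences are capped at 20 000
(seeded subsample) and γ-tuning fits on at most 2000 positives.
Degenerate inputs are handled without failure: zero vectors in
inclination return 0 by the `atan2(0,0)` convention, all-zero windows
produce finite features through log floors, constant sequences yield
zero AR coefficients and zero entropy, and numerically empty soft
assignments fall back to the uniform histogram — each with a warning
where information is lost.

## Known limitations

LDA beyond `n_classes − 1` dimensions is not supported (capped);
orientation filtering is a simple complementary filter, so fast
tumbling motion degrades the two-channel representation; the codebook
front-end does not cover virtual channels; no temporal smoothing is
applied over window decisions; and the hyperparameter grid search is
exhaustive rather than adaptive.
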