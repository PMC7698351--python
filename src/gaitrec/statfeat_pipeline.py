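"""Statistical feature battery computed per time-window.

The classical recognition recipe: compute a fixed battery of features
on every channel sequence of a time-window (MFCC, autoregressive
coefficients, signal magnitude area, variance, entropy, channel
correlations, 75th percentile, extrema, gyro integration and gradient
channels), concatenate them into one large vector, then compress that
vector with a single analytical transformation before classification.

Derived channels (acceleration magnitude, gyroscope magnitude,
inclination, inclination gradient, per-channel gradients) are computed
on the fly from the window's raw channels, exactly like the virtual
sensors concept; inclination always uses raw device-frame acceleration.

The MFCC filter-bank here is parametrised by the filter count ``n_mel``
and a growth factor ``psi``: triangular filters tile 0..Nyquist with
bandwidths growing geometrically by ``psi`` from low to high frequency,
so larger growth factors concentrate resolution in the low frequencies
where gait lives.  Log filter energies are decorrelated with an
orthonormal type-II DCT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from statsmodels.regression.linear_model import burg as _burg
from statsmodels.regression.linear_model import yule_walker as _yule_walker

from . import analytic_pipeline
from .virtual_sensors import inclination_stream  # noqa: F401  (re-export convenience)
from .windowing import TimeWindow

__all__ = [
    "MfccConfig",
    "ArConfig",
    "StatFeatConfig",
    "FeatureLayout",
    "mfcc",
    "mfcc_filterbank",
    "ar_coefficients",
    "sma",
    "entropy",
    "correlation",
    "percentile75",
    "build_layout",
    "assemble_features",
    "reduce_features",
]

_LOG_FLOOR = 1e-12


@dataclass
class MfccConfig:
    """MFCC filter-bank settings: ``n_mel`` filters growing by ``psi``."""

    n_mel: int = 10
    psi: float = 1.6
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.n_mel < 1:
            raise ValueError("n_mel must be >= 1")
        if self.psi < 1:
            raise ValueError("psi must be >= 1")


@dataclass
class ArConfig:
    """Autoregressive model order |q| and estimation method."""

    order: int = 5
    method: str = "yule_walker"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.method not in ("yule_walker", "burg"):
            raise ValueError("method must be 'yule_walker' or 'burg'")


@dataclass
class StatFeatConfig:
    """Full configuration of the statistical-features pipeline."""

    mfcc: MfccConfig = field(default_factory=MfccConfig)
    ar: ArConfig = field(default_factory=ArConfig)
    accel_convention: str = "raw"  # "raw" | "two_channel"

    def __post_init__(self) -> None:
        if self.accel_convention not in ("raw", "two_channel"):
            raise ValueError("accel_convention must be 'raw' or 'two_channel'")


@dataclass
class FeatureLayout:
    """Ordered (feature, source, dims) rows; deterministic per convention."""

    rows: list[tuple[str, str, int]]

    @property
    def total_dims(self) -> int:
        return sum(r[2] for r in self.rows)


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------

def mfcc_filterbank(
    n_bins: int, sample_rate: float, config: MfccConfig
) -> np.ndarray:
    """Triangular filter matrix ``(n_mel, n_bins)`` over rfft bins.

    Edge frequencies ``e_0 = 0 < e_1 < ... < e_{n_mel+1} = Nyquist`` are
    spaced with gaps growing geometrically by ``psi``; filter ``i`` is
    the triangle on ``[e_{i-1}, e_{i+1}]`` peaking at ``e_i``.  With
    ``normalized`` each filter is scaled to unit area.
    """
    nyquist = sample_rate / 2.0
    m = config.n_mel + 1
    if config.psi == 1.0:
        gaps = np.full(m, nyquist / m)
    else:
        g0 = nyquist * (config.psi - 1.0) / (config.psi**m - 1.0)
        gaps = g0 * config.psi ** np.arange(m)
    edges = np.concatenate([[0.0], np.cumsum(gaps)])
    edges[-1] = nyquist
    freqs = np.linspace(0.0, nyquist, n_bins)
    fb = np.zeros((config.n_mel, n_bins))
    for i in range(1, config.n_mel + 1):
        lo, mid, hi = edges[i - 1], edges[i], edges[i + 1]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[i - 1] = np.clip(np.minimum(up, down), 0.0, None)
        if config.normalized:
            fb[i - 1] *= 2.0 / max(hi - lo, 1e-12)
    return fb


def mfcc(
    sequence: np.ndarray, sample_rate: float, config: MfccConfig
) -> np.ndarray:
    """MFCC-style coefficients of one sequence.

    Power spectrum -> geometric-growth triangular filter
    energies -> log (floored at 1e-12) -> orthonormal DCT-II.  Output
    has ``n_mel`` dimensions for any input; an all-zero sequence yields
    a finite vector via the log floor.
    """
    x = np.asarray(sequence, dtype=float)
    if x.shape[0] < 16:
        raise ValueError("sequence must have at least 16 samples")
    # no taper: the sequences are short, the bank is coarse, and an
    # untapered magnitude spectrum keeps periodic signals shift-tolerant
    spec = np.abs(scipy.fft.rfft(x)) ** 2
    fb = mfcc_filterbank(spec.shape[0], sample_rate, config)
    energies = np.log(np.maximum(fb @ spec, _LOG_FLOOR))
    return scipy.fft.dct(energies, type=2, norm="ortho")


def ar_coefficients(sequence: np.ndarray, config: ArConfig) -> np.ndarray:
    """Autoregressive coefficients of order |q|.

    Yule-Walker with biased (1/N) autocovariances by default; Burg
    selectable.  A constant sequence has zero lag-0 variance and
    returns zeros with a warning.
    """
    x = np.asarray(sequence, dtype=float)
    if x.shape[0] <= config.order:
        raise ValueError("sequence must be longer than the model order")
    if float(np.var(x)) < 1e-24:
        warnings.warn("constant sequence; AR coefficients set to 0", stacklevel=2)
        return np.zeros(config.order)
    if config.method == "burg":
        rho, _ = _burg(x, order=config.order, demean=True)
    else:
        rho, _ = _yule_walker(x, order=config.order, method="mle")
    return np.asarray(rho, dtype=float)


def sma(channels: np.ndarray) -> float:
    """Signal magnitude area: mean over time of the summed absolute
    channel values, ``(1/w) * sum_t sum_c |x_c[t]|``."""
    ch = np.atleast_2d(np.asarray(channels, dtype=float))
    return float(np.abs(ch).sum(axis=0).mean())


def entropy(sequence: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the 256-bin histogram over [min, max].

    Equal-width bins on the window's own range; a constant sequence
    occupies a single bin and has zero entropy.  Bounded by
    ``log2(bins)`` = 8 bits.
    """
    x = np.asarray(sequence, dtype=float)
    if x.size == 0:
        raise ValueError("empty sequence")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-300:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def correlation(channels: np.ndarray) -> np.ndarray:
    """Pearson correlation of each unordered channel pair.

    ``n`` channels give ``n (n - 1) / 2`` dimensions in lexicographic
    pair order.  Undefined correlations (a zero-variance channel) are
    reported as 0 with a warning.
    """
    ch = np.atleast_2d(np.asarray(channels, dtype=float))
    n = ch.shape[0]
    if n < 2:
        return np.zeros(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(ch)
    out = np.array([cm[i, j] for i in range(n) for j in range(i + 1, n)])
    if np.any(~np.isfinite(out)):
        warnings.warn(
            "zero-variance channel; undefined correlations set to 0", stacklevel=2
        )
        out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return out


def percentile75(sequence: np.ndarray) -> float:
    """75th percentile by linear interpolation at rank 0.75 (w - 1)."""
    return float(np.percentile(np.asarray(sequence, dtype=float), 75.0))


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def build_layout(config: StatFeatConfig) -> FeatureLayout:
    """The deterministic feature layout for the configured convention.

    Acceleration rows carry 3 channels for raw device-frame data and 2
    for the two-channel convention (with a single correlation pair
    collapsing to 1 dimension).
    """
    n_acc = 3 if config.accel_convention == "raw" else 2
    nm, q = config.mfcc.n_mel, config.ar.order
    rows = [
        ("mfcc", "accel", n_acc * nm),
        ("mfcc", "gyro", 3 * nm),
        ("mfcc", "accel_magnitude", nm),
        ("mfcc", "gyro_magnitude", nm),
        ("ar", "accel", n_acc * q),
        ("sma", "accel", 1),
        ("sma", "gyro", 1),
        ("integration", "gyro", 3),
        ("variance", "inclination", 2),
        ("variance", "accel_magnitude", 1),
        ("variance", "gyro_magnitude", 1),
        ("max", "inclination", 2),
        ("max", "inclination_gradient", 2),
        ("min", "inclination", 2),
        ("min", "inclination_gradient", 2),
        ("entropy", "accel", n_acc),
        ("entropy", "gyro", 3),
        ("correlation", "accel", n_acc * (n_acc - 1) // 2),
        ("correlation", "gyro", 3),
        ("percentile75", "accel_magnitude", 1),
        ("percentile75", "gyro_magnitude", 1),
    ]
    return FeatureLayout(rows)


def _window_sources(window: TimeWindow, config: StatFeatConfig) -> dict[str, np.ndarray]:
    """Gather raw and derived source channels for one window."""
    def grab(names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in window.channel_names]
        if missing:
            raise KeyError(f"window is missing channel(s) {missing}")
        return np.vstack([window.channel(n) for n in names])

    raw_acc = grab(["acc_x", "acc_y", "acc_z"])
    gyro = grab(["gyro_x", "gyro_y", "gyro_z"])
    if config.accel_convention == "two_channel":
        acc = grab(["acc2_v", "acc2_h"])
    else:
        acc = raw_acc
    incl = np.vstack(
        [np.arctan2(raw_acc[1], raw_acc[2]), np.arctan2(raw_acc[0], raw_acc[2])]
    )
    return {
        "accel": acc,
        "gyro": gyro,
        "accel_magnitude": np.linalg.norm(acc, axis=0)[None, :],
        "gyro_magnitude": np.linalg.norm(gyro, axis=0)[None, :],
        "inclination": incl,
        "inclination_gradient": np.diff(incl, axis=1),
    }


def assemble_features(window: TimeWindow, config: StatFeatConfig) -> np.ndarray:
    """Concatenate the full feature battery of one time-window.

    The output dimension equals ``build_layout(config).total_dims``;
    degenerate (e.g. all-zero) windows produce finite vectors through
    the log floors and zero-variance fallbacks.
    """
    src = _window_sources(window, config)
    dt = 1.0 / window.sample_rate
    parts: list[np.ndarray] = []
    for feature, source, dims in build_layout(config).rows:
        ch = src[source]
        if feature == "mfcc":
            block = np.concatenate(
                [mfcc(row, window.sample_rate, config.mfcc) for row in ch]
            )
        elif feature == "ar":
            block = np.concatenate([ar_coefficients(row, config.ar) for row in ch])
        elif feature == "sma":
            block = np.array([sma(ch)])
        elif feature == "integration":
            block = ch.sum(axis=1) * dt
        elif feature == "variance":
            block = ch.var(axis=1)
        elif feature == "max":
            block = ch.max(axis=1)
        elif feature == "min":
            block = ch.min(axis=1)
        elif feature == "entropy":
            block = np.array([entropy(row) for row in ch])
        elif feature == "correlation":
            block = correlation(ch)
        elif feature == "percentile75":
            block = np.array([percentile75(row) for row in ch])
        else:  # pragma: no cover
            raise ValueError(f"unknown feature {feature!r}")
        if block.shape[0] != dims:
            raise RuntimeError(
                f"{feature}/{source} produced {block.shape[0]} dims, "
                f"layout says {dims}"
            )
        parts.append(block)
    return np.concatenate(parts)


def reduce_features(
    features_by_class: dict[str, np.ndarray],
    method: str = "lda",
    d: int = 5,
) -> tuple[analytic_pipeline.ChannelTransform, dict[str, np.ndarray]]:
    """Compress concatenated feature vectors with one analytical transform.

    Reuses the per-channel transform machinery on the whole feature
    vector (a single transform, not per channel).  Returns the fitted
    transform and the reduced vectors per class.
    """
    transform = analytic_pipeline.fit_channel_transform(
        features_by_class, method=method, d=d, channel_name="statfeat"
    )
    reduced = {
        label: np.vstack([transform.project(row) for row in np.atleast_2d(X)])
        for label, X in features_by_class.items()
    }
    return transform, reduced
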