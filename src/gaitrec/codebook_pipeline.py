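"""Codebook (bag-of-codewords) feature learning for sensor sequences.

A codebook is a set of characteristic subsequence shapes (codewords)
learned by clustering training subsequences; one codebook is trained
per sensor on the pooled subsequences of its channels.  During
operation every subsequence of an incoming sequence is *soft-assigned*
to all codewords with Gaussian-kernel weights of smoothness ``sigma``,
and the per-subsequence assignments are averaged into a histogram
feature vector that sums to one.

Two strategies combine a sensor's channels:

* ``independent`` — each channel's subsequences are assigned separately
  with the shared codebook, giving one histogram per channel (three per
  three-channel sensor);
* ``append`` — temporally matching subsequences of all channels are
  concatenated before assignment against a codebook of correspondingly
  longer codewords, giving a single histogram per sensor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans

from .sensor_model import SensorStream
from .windowing import SubseqConfig, TimeWindow

__all__ = [
    "Codebook",
    "train_codebook",
    "soft_assign",
    "soft_assign_batch",
    "window_histogram",
    "stream_features",
    "codebook_to_json",
    "codebook_from_json",
]


@dataclass
class Codebook:
    """Learned codeword set plus assignment smoothness.

    ``codewords`` has shape ``(|C|, w_sub)`` (or ``(|C|, 3 * w_sub)``
    for the append strategy); ``sigma`` > 0 controls the kernel density
    estimation's smoothness during soft assignment.
    """

    codewords: np.ndarray
    sigma: float
    sensor: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.codewords = np.atleast_2d(np.asarray(self.codewords, dtype=float))
        if self.codewords.shape[0] < 1:
            raise ValueError("codebook needs at least one codeword")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    @property
    def size(self) -> int:
        return self.codewords.shape[0]

    @property
    def w_sub(self) -> int:
        return self.codewords.shape[1]


def train_codebook(
    subsequences: np.ndarray,
    size: int,
    sigma: float,
    seed: int = 0,
    sensor: str = "",
    n_restarts: int = 10,
) -> Codebook:
    """Learn ``size`` codewords as k-means cluster centres.

    k-means++ initialisation with ``n_restarts`` restarts; deterministic
    for a given seed.  Raises if fewer subsequences than codewords are
    provided.
    """
    X = np.atleast_2d(np.asarray(subsequences, dtype=float))
    if X.shape[0] < size:
        raise ValueError(
            f"need at least |C|={size} subsequences, got {X.shape[0]}"
        )
    km = KMeans(
        n_clusters=size,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
    ).fit(X)
    return Codebook(km.cluster_centers_, sigma, sensor=sensor, seed=seed)


def soft_assign(subsequence: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Gaussian-kernel soft assignment of one subsequence.

    Weights are proportional to ``exp(-d^2 / (2 sigma^2))`` with
    Euclidean distance ``d`` to each codeword, normalised to sum to 1.
    """
    x = np.asarray(subsequence, dtype=float)
    if x.shape[0] != codebook.w_sub:
        raise ValueError(
            f"subsequence length {x.shape[0]} != codeword length {codebook.w_sub}"
        )
    return soft_assign_batch(x[None, :], codebook)[0]


def soft_assign_batch(subsequences: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Vectorised soft assignment; rows of the result sum to 1."""
    X = np.atleast_2d(np.asarray(subsequences, dtype=float))
    if X.shape[1] != codebook.w_sub:
        raise ValueError(
            f"subsequence length {X.shape[1]} != codeword length {codebook.w_sub}"
        )
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ codebook.codewords.T
        + (codebook.codewords**2).sum(axis=1)[None, :]
    )
    np.clip(d2, 0.0, None, out=d2)
    # subtracting the row minimum leaves the normalised weights unchanged
    # and guarantees at least one weight of exp(0) = 1 per row
    z = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * codebook.sigma**2))
    totals = z.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(totals[:, 0]) | (totals[:, 0] <= 0)
    if np.any(bad):
        warnings.warn(
            "numerically degenerate soft assignment; using uniform weights",
            stacklevel=2,
        )
        z[bad] = 1.0
        totals = z.sum(axis=1, keepdims=True)
    return z / totals


def _channels_by_sensor(
    channel_names: list[str], sensors: list[str]
) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for sensor in sensors:
        idx = [
            i
            for i, name in enumerate(channel_names)
            if name == sensor or name.startswith(sensor + "_")
        ]
        if not idx:
            raise ValueError(f"no channels found for sensor {sensor!r}")
        groups[sensor] = idx
    return groups


def _subsequence_matrix(seq: np.ndarray, cfg: SubseqConfig) -> np.ndarray:
    """The ``(n_sub, w_sub)`` subsequences of one sequence at stride s_i."""
    need = cfg.sequence_length()
    if seq.shape[0] < need:
        raise ValueError(
            f"sequence of {seq.shape[0]} samples shorter than w_seq={need}"
        )
    views = sliding_window_view(seq, cfg.w_sub)
    return views[: (cfg.n_sub - 1) * cfg.s_i + 1 : cfg.s_i]


def training_subsequences(
    windows: list[TimeWindow], sensor: str, cfg: SubseqConfig, strategy: str = "independent"
) -> np.ndarray:
    """Collect codebook training subsequences from labelled windows.

    ``independent`` pools the subsequences of all the sensor's channels;
    ``append`` concatenates temporally matching subsequences across
    channels.
    """
    out = []
    for win in windows:
        idx = _channels_by_sensor(win.channel_names, [sensor])[sensor]
        subs = [_subsequence_matrix(win.data[i], cfg) for i in idx]
        if strategy == "independent":
            out.extend(subs)
        elif strategy == "append":
            out.append(np.concatenate(subs, axis=1))
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return np.vstack(out)


def window_histogram(
    window: TimeWindow,
    codebooks: dict[str, Codebook],
    cfg: SubseqConfig,
    strategy: str = "independent",
) -> list[np.ndarray]:
    """Histogram feature vectors of one time-window.

    Returns one simplex vector per channel (``independent``) or one per
    sensor (``append``), ordered by sensor and then channel.  The
    window's width must equal the sequence length implied by the
    subsequence geometry.
    """
    if strategy not in ("independent", "append"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if window.width != cfg.sequence_length():
        raise ValueError(
            f"window width {window.width} != w_seq={cfg.sequence_length()}"
        )
    groups = _channels_by_sensor(window.channel_names, list(codebooks))
    out: list[np.ndarray] = []
    for sensor, idx in groups.items():
        cb = codebooks[sensor]
        subs = [_subsequence_matrix(window.data[i], cfg) for i in idx]
        if strategy == "independent":
            if cb.w_sub != cfg.w_sub:
                raise ValueError(
                    f"codebook {sensor!r} has codeword length {cb.w_sub}, "
                    f"expected w_sub={cfg.w_sub}"
                )
            for sub in subs:
                out.append(soft_assign_batch(sub, cb).mean(axis=0))
        else:
            appended = np.concatenate(subs, axis=1)
            if cb.w_sub != appended.shape[1]:
                raise ValueError(
                    f"codebook {sensor!r} has codeword length {cb.w_sub}, "
                    f"append strategy needs {appended.shape[1]}"
                )
            out.append(soft_assign_batch(appended, cb).mean(axis=0))
    return out


def stream_features(
    streams: list[SensorStream],
    codebooks: dict[str, Codebook],
    cfg: SubseqConfig,
    strategy: str = "independent",
) -> tuple[np.ndarray, np.ndarray]:
    """Time-indexed concatenated histogram features over whole streams.

    Sequences advance by a quarter of their contained subsequences
    (``(n_sub / 4) * s_i`` samples), so each subsequence's soft
    assignment is computed once and reused by the four overlapping
    sequences covering it; the result is identical to naive
    recomputation per sequence.

    Returns ``(starts, features)`` where ``starts`` are the sequence
    start indices and ``features`` stacks one concatenated feature
    vector per sequence.
    """
    names = [c for s in streams for c in s.channel_names]
    data = np.vstack([s.samples for s in streams])
    n = data.shape[1]
    w_seq = cfg.sequence_length()
    if n < w_seq:
        raise ValueError(f"stream of {n} samples shorter than w_seq={w_seq}")
    step_sub = cfg.sequence_step_subseq
    step = step_sub * cfg.s_i
    groups = _channels_by_sensor(names, list(codebooks))

    # per-channel (or per-sensor for append) assignments at every
    # subsequence position on the s_i grid, computed once
    n_pos = (n - cfg.w_sub) // cfg.s_i + 1
    assigned: list[np.ndarray] = []
    for sensor, idx in groups.items():
        cb = codebooks[sensor]
        views = [
            sliding_window_view(data[i], cfg.w_sub)[:: cfg.s_i][:n_pos] for i in idx
        ]
        if strategy == "independent":
            assigned.extend(soft_assign_batch(v, cb) for v in views)
        elif strategy == "append":
            assigned.append(soft_assign_batch(np.concatenate(views, axis=1), cb))
        else:
            raise ValueError(f"unknown strategy {strategy!r}")

    starts = np.arange(0, n - w_seq + 1, step)
    feats = []
    # prefix sums turn the per-sequence mean over n_sub assignments into
    # two lookups
    prefixes = [
        np.vstack([np.zeros(a.shape[1]), np.cumsum(a, axis=0)]) for a in assigned
    ]
    for p in starts:
        j = p // cfg.s_i
        parts = [(pre[j + cfg.n_sub] - pre[j]) / cfg.n_sub for pre in prefixes]
        feats.append(np.concatenate(parts))
    return starts, np.vstack(feats)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def codebook_to_json(codebook: Codebook, config_hash: str = "") -> str:
    return json.dumps(
        {
            "codewords": codebook.codewords.tolist(),
            "sigma": codebook.sigma,
            "sensor": codebook.sensor,
            "seed": codebook.seed,
            "config_hash": config_hash,
        }
    )


def codebook_from_json(text: str) -> Codebook:
    payload = json.loads(text)
    return Codebook(
        np.asarray(payload["codewords"]),
        payload["sigma"],
        sensor=payload.get("sensor", ""),
        seed=payload.get("seed"),
    )
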