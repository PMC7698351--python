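"""Per-channel analytical transforms (PCA / multiclass LDA) and embedding.

The core of the analytical-transform recognition approach: every sensor
channel (hardware or virtual) gets its own learned linear projection of
the raw windowed sequences.  A sequence of ``w`` samples is seen as a
``w``-dimensional vector; the transform projects it onto the ``d`` most
significant eigenvectors.  The per-channel projections are concatenated
into one feature vector per time-window for classification.

PCA eigenvectors are the principal axes of the pooled (all classes
together) covariance of the centered training sequences; their
eigenvalues equal the variances along those axes.  The LDA variant is
the multiclass (Rao) formulation: eigenvectors of
``S_w^-1 S_b`` with within-class scatter ``S_w`` and between-class
scatter ``S_b``, which yields at most ``|Omega| - 1`` discriminative
directions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .windowing import TimeWindow

__all__ = [
    "ChannelTransform",
    "fit_channel_transform",
    "embed_time_window",
    "normalize_channel_variance",
    "transforms_to_json",
    "transforms_from_json",
]


@dataclass
class ChannelTransform:
    """Learned linear projection for one sensor channel.

    ``basis`` rows are the most significant eigenvectors in descending
    eigenvalue order; for PCA they are orthonormal and ``eigenvalues``
    are the variances along them.  ``project`` maps a ``w``-sample
    sequence to ``d`` dimensions after subtracting the training mean.
    """

    channel_name: str
    method: str
    mean: np.ndarray
    basis: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.method not in ("pca", "lda"):
            raise ValueError("method must be 'pca' or 'lda'")
        if self.basis.shape[1] != self.mean.shape[0]:
            raise ValueError("basis width must match mean length")
        if self.basis.shape[0] > self.basis.shape[1]:
            raise ValueError("cannot retain more dimensions than the input has")

    @property
    def d(self) -> int:
        return self.basis.shape[0]

    @property
    def w(self) -> int:
        return self.basis.shape[1]

    def project(self, sequence: np.ndarray) -> np.ndarray:
        sequence = np.asarray(sequence, dtype=float)
        return self.basis @ (sequence - self.mean)

    def reconstruct(self, coords: np.ndarray) -> np.ndarray:
        """Back-projection (exact inverse only for PCA with full d)."""
        return self.mean + self.basis.T @ np.asarray(coords, dtype=float)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-magnitude component is positive."""
    out = vectors.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


def fit_channel_transform(
    sequences_by_class: dict[str, np.ndarray],
    method: str = "pca",
    d: int = 5,
    channel_name: str = "",
    ridge: float = 1e-6,
) -> ChannelTransform:
    """Fit a per-channel PCA or multiclass-LDA transform.

    Parameters
    ----------
    sequences_by_class:
        Mapping class label -> ``(n_i, w)`` array of training sequences
        for this channel.  PCA pools all classes; LDA needs >= 2.
    method:
        ``"pca"`` or ``"lda"``.
    d:
        Retained dimensions.  For LDA, capped at ``n_classes - 1`` with
        a warning (the between-class scatter has no more rank).
    ridge:
        Relative ridge added to a (near-)singular within-class scatter.
    """
    if method not in ("pca", "lda"):
        raise ValueError("method must be 'pca' or 'lda'")
    classes = sorted(sequences_by_class)
    blocks = [np.atleast_2d(np.asarray(sequences_by_class[c], float)) for c in classes]
    X = np.vstack(blocks)
    n, w = X.shape
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > w:
        raise ValueError(f"cannot retain d={d} dimensions from w={w}-sample sequences")
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} sequences, got {n}")
    mean = X.mean(axis=0)

    if method == "pca":
        Xc = X - mean
        cov = (Xc.T @ Xc) / n
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:d]
        basis = _fix_signs(evecs[:, order].T)
        eigenvalues = np.clip(evals[order], 0.0, None)
        return ChannelTransform(channel_name, "pca", mean, basis, eigenvalues)

    # multiclass LDA (Rao)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    max_d = len(classes) - 1
    if d > max_d:
        warnings.warn(
            f"LDA retains at most n_classes-1={max_d} dimensions; "
            f"capping requested d={d}",
            stacklevel=2,
        )
        d = max_d
    Sw = np.zeros((w, w))
    Sb = np.zeros((w, w))
    for block in blocks:
        mu = block.mean(axis=0)
        centered = block - mu
        Sw += centered.T @ centered
        diff = (mu - mean)[:, None]
        Sb += block.shape[0] * (diff @ diff.T)
    sw_scale = np.trace(Sw) / w
    min_eig = scipy.linalg.eigh(Sw, eigvals_only=True, subset_by_index=[0, 0])[0]
    if sw_scale == 0 or min_eig < 1e-10 * max(sw_scale, 1.0):
        warnings.warn(
            "within-class scatter is singular; applying ridge regularization",
            stacklevel=2,
        )
        Sw = Sw + ridge * max(sw_scale, 1.0) * np.eye(w)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:d]
    basis = evecs[:, order].T
    basis = basis / np.linalg.norm(basis, axis=1, keepdims=True)
    basis = _fix_signs(basis)
    return ChannelTransform(channel_name, "lda", mean, basis, evals[order])


def embed_time_window(
    window: TimeWindow, transforms: dict[str, ChannelTransform]
) -> np.ndarray:
    """Concatenate per-channel projections into one feature vector.

    Channels are embedded in the window's channel order; the output
    length is the sum of the per-channel retained dimensions.  A channel
    without a transform is an error.
    """
    parts = []
    for i, name in enumerate(window.channel_names):
        if name not in transforms:
            raise KeyError(f"no transform fitted for channel {name!r}")
        parts.append(transforms[name].project(window.data[i]))
    return np.concatenate(parts)


def normalize_channel_variance(sequences: np.ndarray) -> np.ndarray:
    """Scale a channel's sequences to unit pooled variance.

    The pooled variance is the population variance of all samples of all
    sequences around the grand mean.  Pure scaling (no centering), so a
    channel already at unit variance is unchanged and a scaled copy of a
    channel maps to the same output.  A zero-variance channel is left
    unscaled with a warning.
    """
    X = np.atleast_2d(np.asarray(sequences, dtype=float))
    var = float(X.var())
    if var <= 0:
        warnings.warn("zero-variance channel left unscaled", stacklevel=2)
        return X.copy()
    return X / np.sqrt(var)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def transforms_to_json(
    transforms: dict[str, ChannelTransform], config_hash: str = ""
) -> str:
    payload = {
        "config_hash": config_hash,
        "transforms": [
            {
                "channel_name": t.channel_name,
                "method": t.method,
                "mean": t.mean.tolist(),
                "basis": t.basis.tolist(),
                "eigenvalues": t.eigenvalues.tolist(),
            }
            for t in transforms.values()
        ],
    }
    return json.dumps(payload)


def transforms_from_json(text: str) -> dict[str, ChannelTransform]:
    payload = json.loads(text)
    out = {}
    for item in payload["transforms"]:
        t = ChannelTransform(
            item["channel_name"],
            item["method"],
            np.asarray(item["mean"]),
            np.asarray(item["basis"]),
            np.asarray(item["eigenvalues"]),
        )
        out[t.channel_name] = t
    return out
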