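"""Classification, one-class outlier rejection, and evaluation metrics.

The evaluation protocol: windows are split per class into 70% training
and 30% test, a k-nearest-neighbour (k = 3) or RBF-kernel SVM
classifier is fitted on the training features, and results are reported
as a |Omega| x |Omega| confusion matrix from which the *average class
accuracy* (unweighted mean of per-class recalls, robust to class
imbalance) and the macro F1 score derive.

The messing-around rejection class is never trained as a regular class:
a one-class SVM with RBF kernel, fitted only on positive (locomotion)
feature vectors, flags outliers.  Its kernel scale ``gamma`` is tuned
by a coarse log-grid search with local refinement, maximising the
unweighted mean of positive-class and outlier-class accuracies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, OneClassSVM

__all__ = [
    "ConfusionMatrix",
    "ClassifierConfig",
    "OutlierModel",
    "average_class_accuracy",
    "macro_f1",
    "split_train_test",
    "make_classifier",
    "fit_outlier_model",
    "evaluate_outlier",
    "tune_gamma",
]


@dataclass
class ConfusionMatrix:
    """|Omega| x |Omega| integer table; row = actual, column = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.classes = tuple(self.classes)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square with one row per class")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, classes: tuple[str, ...]
    ) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        width = max(max(len(c) for c in self.classes), 6)
        head = " " * width + " " + " ".join(f"{c:>{width}}" for c in self.classes)
        rows = [
            f"{c:>{width}} " + " ".join(f"{v:>{width}d}" for v in row)
            for c, row in zip(self.classes, self.counts)
        ]
        return "\n".join([head, *rows])

    def to_json(self) -> str:
        return json.dumps(
            {"classes": list(self.classes), "counts": self.counts.tolist()}
        )


def average_class_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls, in percent.

    Classes with no actual samples are excluded with a warning; an
    entirely empty matrix is an error.
    """
    row_sums = cm.counts.sum(axis=1)
    present = row_sums > 0
    if not np.any(present):
        raise ValueError("empty confusion matrix")
    if not np.all(present):
        absent = [c for c, p in zip(cm.classes, present) if not p]
        warnings.warn(f"classes without samples excluded: {absent}", stacklevel=2)
    recalls = np.diag(cm.counts)[present] / row_sums[present]
    return float(recalls.mean() * 100.0)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1 scores, in percent.

    A class absent from both actual and predicted samples is excluded
    with a warning; a present class whose precision and recall are both
    zero contributes F1 = 0.
    """
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    f1s = []
    excluded = []
    for i, c in enumerate(cm.classes):
        if row[i] == 0 and col[i] == 0:
            excluded.append(c)
            continue
        prec = diag[i] / col[i] if col[i] > 0 else 0.0
        rec = diag[i] / row[i] if row[i] > 0 else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    if excluded:
        warnings.warn(f"absent classes excluded from macro F1: {excluded}", stacklevel=2)
    if not f1s:
        raise ValueError("empty confusion matrix")
    return float(np.mean(f1s) * 100.0)


def split_train_test(
    items_by_class: dict[str, list],
    train_frac: float = 0.70,
    seed: int = 0,
) -> tuple[dict[str, list], dict[str, list]]:
    """Stratified random 70/30 split, deterministic for a given seed."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: dict[str, list] = {}
    test: dict[str, list] = {}
    for label in sorted(items_by_class):
        items = items_by_class[label]
        order = rng.permutation(len(items))
        n_train = int(round(len(items) * train_frac))
        train[label] = [items[i] for i in order[:n_train]]
        test[label] = [items[i] for i in order[n_train:]]
    return train, test


@dataclass
class ClassifierConfig:
    """Window classifier: kNN (k = 3) or multiclass SVM-RBF.

    The SVM uses the one-vs-one scheme with default regularisation
    (C = 1) and per-feature standardisation; kNN uses plain Euclidean
    distance on the reduced feature vectors.
    """

    kind: str = "svm_rbf"
    k: int = 3
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    probability: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "svm_rbf"):
            raise ValueError("kind must be 'knn' or 'svm_rbf'")


def make_classifier(config: ClassifierConfig):
    """Instantiate the configured scikit-learn classifier."""
    if config.kind == "knn":
        return KNeighborsClassifier(n_neighbors=config.k, metric="euclidean")
    extra = {"probability": True, "random_state": 0} if config.probability else {}
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=config.svm_c,
                    gamma=config.svm_gamma,
                    decision_function_shape="ovo",
                    **extra,
                ),
            ),
        ]
    )


@dataclass
class OutlierModel:
    """One-class SVM novelty detector over positive feature vectors."""

    gamma: float
    nu: float = 0.05
    _svm: OneClassSVM | None = field(default=None, repr=False)

    def detect(self, features: np.ndarray) -> np.ndarray:
        """Boolean inlier mask (True = accepted as a known activity)."""
        if self._svm is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(features, dtype=float))
        return self._svm.predict(X) == 1


def fit_outlier_model(
    positive_features: np.ndarray, gamma: float, nu: float = 0.05
) -> OutlierModel:
    """Train the one-class SVM on positive (activity) features only."""
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    X = np.atleast_2d(np.asarray(positive_features, dtype=float))
    svm = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu).fit(X)
    return OutlierModel(gamma=gamma, nu=nu, _svm=svm)


def evaluate_outlier(
    model: OutlierModel,
    positive_features: np.ndarray,
    outlier_features: np.ndarray,
) -> dict[str, float]:
    """Positive-class accuracy, outlier-class accuracy and their mean (%)."""
    pos = model.detect(positive_features)
    out = ~model.detect(outlier_features)
    pos_acc = float(pos.mean() * 100.0)
    out_acc = float(out.mean() * 100.0)
    return {
        "positive_accuracy": pos_acc,
        "outlier_accuracy": out_acc,
        "mean_accuracy": (pos_acc + out_acc) / 2.0,
    }


def tune_gamma(
    positive_features: np.ndarray,
    outlier_features: np.ndarray,
    nu: float = 0.05,
    val_frac: float = 0.3,
    seed: int = 0,
    coarse_grid: np.ndarray | None = None,
    refine_rounds: int = 2,
    refine_points: int = 5,
    max_fit: int = 2000,
) -> tuple[float, dict[str, float]]:
    """Search the RBF scale gamma maximising mean class accuracy.

    Deterministic coarse log-grid search followed by local geometric
    refinement around the best point.  Positives are split into a fit
    and a validation part; the outlier set is used for validation only.
    Returns the best gamma and its accuracy decomposition.
    """
    pos = np.atleast_2d(np.asarray(positive_features, dtype=float))
    out = np.atleast_2d(np.asarray(outlier_features, dtype=float))
    rng = np.random.default_rng(seed)
    order = rng.permutation(pos.shape[0])
    n_val = max(1, int(round(pos.shape[0] * val_frac)))
    val, fit = pos[order[:n_val]], pos[order[n_val:]]
    if fit.shape[0] > max_fit:
        fit = fit[rng.permutation(fit.shape[0])[:max_fit]]

    if coarse_grid is None:
        coarse_grid = np.logspace(-4, 3, 15)

    def objective(gamma: float) -> dict[str, float]:
        model = fit_outlier_model(fit, gamma, nu=nu)
        return evaluate_outlier(model, val, out)

    results: dict[float, dict[str, float]] = {}

    def score(gamma: float) -> float:
        g = float(gamma)
        if g not in results:
            results[g] = objective(g)
        return results[g]["mean_accuracy"]

    best = max(coarse_grid, key=score)
    span = coarse_grid[1] / coarse_grid[0] if len(coarse_grid) > 1 else 10.0
    for _ in range(refine_rounds):
        span = span ** (2.0 / (refine_points - 1))
        local = best * span ** (np.arange(refine_points) - refine_points // 2)
        best = max(local, key=score)
    best = float(best)
    return best, results[best]
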