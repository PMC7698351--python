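"""End-to-end training/evaluation harness for the three pipelines.

Glue between the feature modules and the evaluation protocol: build the
channel set of a recording, extract per-class windows with boundary
overlap, split 70/30 per class, fit the pipeline's feature extractor on
the training windows, classify the four locomotion classes, and run the
one-class outlier stage against the messing-around windows.

``run_benchmark`` trains one model on the pooled training windows of
all supplied carry modes and evaluates each mode separately (plus the
pooled result), mirroring the combined-training protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import analytic_pipeline, classify_eval, codebook_pipeline, statfeat_pipeline
from .classify_eval import ClassifierConfig, ConfusionMatrix
from .sensor_model import (
    Recording,
    SensorStream,
    estimate_orientation,
    two_channel_stream,
)
from .statfeat_pipeline import StatFeatConfig
from .synthetic_data import BenchmarkSuite
from .virtual_sensors import align_streams, default_virtual_sensors
from .windowing import (
    LOCOMOTION_ACTIVITIES,
    OUTLIER_ACTIVITY,
    SubseqConfig,
    TimeWindow,
    WindowConfig,
    extract_training_segments,
    segments_from_seconds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalyticConfig",
    "CodebookConfig",
    "StatFeatRunConfig",
    "PipelineResult",
    "build_channel_set",
    "collect_windows",
    "run_benchmark",
    "hyperparameter_grids",
    "grid_search",
]

#: Default one-class RBF scales per pipeline (starting points for tuning).
DEFAULT_OUTLIER_GAMMA = {"analytic": 0.005, "codebook": 15.0, "statfeat": 4.55}


# ---------------------------------------------------------------------------
# pipeline configurations
# ---------------------------------------------------------------------------

@dataclass
class AnalyticConfig:
    """Best-performing analytical-transform configuration by default:
    PCA with 5 retained dimensions per channel, 2 s windows, raw
    acceleration, all virtual sensors."""

    method: str = "pca"
    d: int = 5
    window_seconds: float = 2.0
    accel_variant: str = "raw"  # "raw" | "two_channel"
    include_virtual: bool = True
    w_virt: int = 15

    name = "analytic"


@dataclass
class CodebookConfig:
    """Default codebook configuration: sigma = 0.25, |C| = 32,
    w_sub = 32, n_sub = 32, s_i = 2, raw acceleration, the
    channel-independent assignment strategy."""

    sigma: float = 0.25
    size: int = 32
    subseq: SubseqConfig = field(default_factory=SubseqConfig)
    strategy: str = "independent"
    max_train_subsequences: int = 20000

    name = "codebook"


@dataclass
class StatFeatRunConfig:
    """Default statistical-features configuration: 2.5 s windows,
    LDA-reduced concatenated features, two-channel acceleration,
    n_mel = 10, psi = 1.6, |q| = 5."""

    features: StatFeatConfig = field(
        default_factory=lambda: StatFeatConfig(accel_convention="two_channel")
    )
    method: str = "lda"
    d: int = 5
    window_seconds: float = 2.5

    name = "statfeat"


@dataclass
class PipelineResult:
    """Evaluation report of one pipeline run."""

    pipeline: str
    confusion: dict[str, ConfusionMatrix]
    accuracy: dict[str, float]
    macro_f1: dict[str, float]
    outlier: dict[str, float]
    outlier_gamma: float
    n_train: int
    n_test: int


# ---------------------------------------------------------------------------
# channel assembly and window collection
# ---------------------------------------------------------------------------

def build_channel_set(
    recording: Recording,
    accel_variant: str = "raw",
    include_virtual: bool = True,
    w_virt: int = 15,
    include_raw_accel: bool = True,
) -> list[SensorStream]:
    """Aligned channel set of one recording.

    ``accel_variant="two_channel"`` adds the orientation-aligned
    two-channel acceleration (complementary filter) and uses it for the
    windowed virtual sensors; inclination always consumes the raw
    device-frame acceleration.
    """
    accel, gyro = recording.accel, recording.gyro
    streams: list[SensorStream] = []
    if accel_variant == "two_channel":
        orientations = estimate_orientation(accel, gyro)
        acc2 = two_channel_stream(accel, orientations)
        if include_raw_accel:
            streams.append(accel)
        streams.append(acc2)
        feature_accel = acc2
    elif accel_variant == "raw":
        streams.append(accel)
        feature_accel = accel
    else:
        raise ValueError(f"unknown accel_variant {accel_variant!r}")
    streams.append(gyro)
    if include_virtual:
        streams.extend(
            default_virtual_sensors(feature_accel, gyro, raw_accel=accel, w_virt=w_virt)
        )
    return align_streams(streams)


def collect_windows(
    recordings: list[Recording],
    window_cfg: WindowConfig,
    channel_builder: Callable[[Recording], list[SensorStream]],
) -> dict[str, list[TimeWindow]]:
    """Per-class time-windows pooled over recordings."""
    out: dict[str, list[TimeWindow]] = {}
    for rec in recordings:
        streams = align_streams(channel_builder(rec))
        segments = segments_from_seconds(rec.labels, streams[0])
        for label, windows in extract_training_segments(
            streams, segments, window_cfg
        ).items():
            out.setdefault(label, []).extend(windows)
    return out


# ---------------------------------------------------------------------------
# per-pipeline featurization
# ---------------------------------------------------------------------------

def _fit_analytic(train: dict[str, np.ndarray], cfg: AnalyticConfig, windows):
    channel_names = windows[0].channel_names
    transforms = {}
    for i, name in enumerate(channel_names):
        seqs_by_class = {
            label: np.stack([w.data[i] for w in ws])
            for label, ws in train.items()
            if ws
        }
        transforms[name] = analytic_pipeline.fit_channel_transform(
            seqs_by_class, method=cfg.method, d=cfg.d, channel_name=name
        )
    return lambda ws: np.vstack(
        [analytic_pipeline.embed_time_window(w, transforms) for w in ws]
    )


def _fit_codebook(train: dict[str, list[TimeWindow]], cfg: CodebookConfig, seed: int):
    pooled = [w for ws in train.values() for w in ws]
    rng = np.random.default_rng(seed)
    codebooks = {}
    for sensor in ("acc", "gyro"):
        subs = codebook_pipeline.training_subsequences(
            pooled, sensor, cfg.subseq, strategy=cfg.strategy
        )
        if subs.shape[0] > cfg.max_train_subsequences:
            keep = rng.choice(
                subs.shape[0], cfg.max_train_subsequences, replace=False
            )
            subs = subs[np.sort(keep)]
        codebooks[sensor] = codebook_pipeline.train_codebook(
            subs, cfg.size, cfg.sigma, seed=seed, sensor=sensor
        )

    def featurize(ws: list[TimeWindow]) -> np.ndarray:
        return np.vstack(
            [
                np.concatenate(
                    codebook_pipeline.window_histogram(
                        w, codebooks, cfg.subseq, strategy=cfg.strategy
                    )
                )
                for w in ws
            ]
        )

    return featurize


def _fit_statfeat(train: dict[str, list[TimeWindow]], cfg: StatFeatRunConfig):
    raw_by_class = {
        label: np.vstack(
            [statfeat_pipeline.assemble_features(w, cfg.features) for w in ws]
        )
        for label, ws in train.items()
        if ws
    }
    transform, _ = statfeat_pipeline.reduce_features(
        raw_by_class, method=cfg.method, d=cfg.d
    )

    def featurize(ws: list[TimeWindow]) -> np.ndarray:
        return np.vstack(
            [
                transform.project(
                    statfeat_pipeline.assemble_features(w, cfg.features)
                )
                for w in ws
            ]
        )

    return featurize


# ---------------------------------------------------------------------------
# benchmark runner
# ---------------------------------------------------------------------------

def _window_config(cfg) -> WindowConfig:
    if isinstance(cfg, CodebookConfig):
        return WindowConfig(
            window_samples=cfg.subseq.sequence_length(),
            step_samples=cfg.subseq.sequence_step_samples,
        )
    return WindowConfig(window_seconds=cfg.window_seconds)


def _channel_builder(cfg) -> Callable[[Recording], list[SensorStream]]:
    if isinstance(cfg, AnalyticConfig):
        return lambda rec: build_channel_set(
            rec,
            accel_variant=cfg.accel_variant,
            include_virtual=cfg.include_virtual,
            w_virt=cfg.w_virt,
            include_raw_accel=False,
        )
    if isinstance(cfg, CodebookConfig):
        return lambda rec: [rec.accel, rec.gyro]
    two = cfg.features.accel_convention == "two_channel"
    return lambda rec: build_channel_set(
        rec,
        accel_variant="two_channel" if two else "raw",
        include_virtual=False,
        include_raw_accel=True,
    )


def run_benchmark(
    recordings_by_mode: dict[str, list[Recording]] | BenchmarkSuite,
    pipeline_cfg=None,
    classifier: ClassifierConfig | None = None,
    seed: int = 0,
    tune_outlier: bool = True,
) -> PipelineResult:
    """Train one pipeline on pooled modes, evaluate per mode and pooled.

    Steps: collect per-class windows per mode, 70/30 stratified split,
    fit the feature extractor on pooled training windows of the four
    locomotion classes, classify the test windows, and evaluate the
    one-class outlier stage (trained on locomotion features, tuned on
    the training split, tested against held-out messing-around
    windows).
    """
    if isinstance(recordings_by_mode, BenchmarkSuite):
        recordings_by_mode = recordings_by_mode.recordings
    cfg = pipeline_cfg if pipeline_cfg is not None else AnalyticConfig()
    classifier = classifier or ClassifierConfig()
    window_cfg = _window_config(cfg)
    builder = _channel_builder(cfg)

    train_by_mode, test_by_mode = {}, {}
    for mode in sorted(recordings_by_mode):
        windows = collect_windows(recordings_by_mode[mode], window_cfg, builder)
        train, test = classify_eval.split_train_test(windows, seed=seed)
        train_by_mode[mode], test_by_mode[mode] = train, test

    def pooled(split_by_mode):
        out: dict[str, list[TimeWindow]] = {}
        for split in split_by_mode.values():
            for label, ws in split.items():
                out.setdefault(label, []).extend(ws)
        return out

    train = pooled(train_by_mode)
    train_loco = {k: v for k, v in train.items() if k in LOCOMOTION_ACTIVITIES}

    if isinstance(cfg, AnalyticConfig):
        featurize = _fit_analytic(
            train_loco, cfg, next(ws for ws in train_loco.values() if ws)
        )
    elif isinstance(cfg, CodebookConfig):
        featurize = _fit_codebook(train_loco, cfg, seed)
    elif isinstance(cfg, StatFeatRunConfig):
        featurize = _fit_statfeat(train_loco, cfg)
    else:
        raise TypeError(f"unknown pipeline config {type(cfg).__name__}")

    x_train = featurize([w for ws in train_loco.values() for w in ws])
    y_train = np.concatenate(
        [[label] * len(ws) for label, ws in train_loco.items() if ws]
    )
    model = classify_eval.make_classifier(classifier)
    model.fit(x_train, y_train)

    confusion, accuracy, f1 = {}, {}, {}
    pooled_true, pooled_pred = [], []
    for mode, test in test_by_mode.items():
        test_loco = {k: v for k, v in test.items() if k in LOCOMOTION_ACTIVITIES}
        x_test = featurize([w for ws in test_loco.values() for w in ws])
        y_test = np.concatenate(
            [[label] * len(ws) for label, ws in test_loco.items() if ws]
        )
        y_pred = model.predict(x_test)
        cm = ConfusionMatrix.from_predictions(
            y_test, y_pred, LOCOMOTION_ACTIVITIES
        )
        confusion[mode] = cm
        accuracy[mode] = classify_eval.average_class_accuracy(cm)
        f1[mode] = classify_eval.macro_f1(cm)
        pooled_true.extend(y_test)
        pooled_pred.extend(y_pred)
    cm_all = ConfusionMatrix.from_predictions(
        pooled_true, pooled_pred, LOCOMOTION_ACTIVITIES
    )
    confusion["combined"] = cm_all
    accuracy["combined"] = classify_eval.average_class_accuracy(cm_all)
    f1["combined"] = classify_eval.macro_f1(cm_all)

    # outlier stage: one-class SVM on locomotion features vs messing-around
    outlier_report: dict[str, float] = {}
    gamma = DEFAULT_OUTLIER_GAMMA.get(cfg.name, 1.0)
    train_out = [w for w in train.get(OUTLIER_ACTIVITY, [])]
    test_all = pooled(test_by_mode)
    test_out = test_all.get(OUTLIER_ACTIVITY, [])
    if train_out and test_out:
        x_out_train = featurize(train_out)
        if tune_outlier:
            gamma, _ = classify_eval.tune_gamma(
                x_train, x_out_train, seed=seed
            )
        outlier_model = classify_eval.fit_outlier_model(x_train, gamma)
        x_test_loco = featurize(
            [w for k, ws in test_all.items() if k in LOCOMOTION_ACTIVITIES for w in ws]
        )
        outlier_report = classify_eval.evaluate_outlier(
            outlier_model, x_test_loco, featurize(test_out)
        )
    else:
        logger.warning("no messing-around windows; outlier stage skipped")

    return PipelineResult(
        pipeline=cfg.name,
        confusion=confusion,
        accuracy=accuracy,
        macro_f1=f1,
        outlier=outlier_report,
        outlier_gamma=gamma,
        n_train=len(y_train),
        n_test=len(pooled_true),
    )


# ---------------------------------------------------------------------------
# hyperparameter tuning harness
# ---------------------------------------------------------------------------

def hyperparameter_grids() -> dict[str, dict[str, list]]:
    """The evaluation's hyperparameter grids, per pipeline."""
    return {
        "analytic": {
            "window_seconds": [2.0, 2.5, 3.0],
            "d": [3, 4, 5],
            "method": ["pca", "lda"],
            "accel_variant": ["raw", "two_channel"],
        },
        "codebook": {
            "sigma": [0.25, 0.5],
            "size": [16, 32, 64],
            "w_sub": [32, 48, 64, 96],
        },
        "statfeat": {
            "window_seconds": [2.0, 2.5, 3.0],
            "d": [3, 4, 5, 6, 7],
            "n_mel": [3, 5, 10, 15],
            "psi": [round(1.2 + 0.1 * i, 1) for i in range(9)],
            "q": [3, 5, 10, 15],
        },
    }


def _make_cfg(pipeline: str, params: dict):
    if pipeline == "analytic":
        return AnalyticConfig(**params)
    if pipeline == "codebook":
        sub = SubseqConfig(w_sub=params.pop("w_sub", 32))
        return CodebookConfig(subseq=sub, **params)
    if pipeline == "statfeat":
        feats = StatFeatConfig(accel_convention="two_channel")
        if "n_mel" in params:
            feats.mfcc.n_mel = params.pop("n_mel")
        if "psi" in params:
            feats.mfcc.psi = params.pop("psi")
        if "q" in params:
            feats.ar.order = params.pop("q")
        return StatFeatRunConfig(features=feats, **params)
    raise ValueError(f"unknown pipeline {pipeline!r}")


def grid_search(
    recordings_by_mode,
    pipeline: str,
    grid: dict[str, list],
    classifier: ClassifierConfig | None = None,
    seed: int = 0,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Exhaustive, reproducible search over a hyperparameter grid.

    Returns the best parameter set (by combined average class accuracy)
    and the full (params, accuracy) table.  Defaults to the fast kNN
    classifier, mirroring the benchmarking protocol.
    """
    import itertools

    classifier = classifier or ClassifierConfig(kind="knn", k=3)
    names = sorted(grid)
    table = []
    for values in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, values))
        cfg = _make_cfg(pipeline, dict(params))
        result = run_benchmark(
            recordings_by_mode,
            cfg,
            classifier=classifier,
            seed=seed,
            tune_outlier=False,
        )
        table.append((params, result.accuracy["combined"]))
    best = max(table, key=lambda item: item[1])[0]
    return best, table
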