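"""Sliding-window extraction, training-segment handling, sequence geometry.

All indexing is 0-based and half-open.  A *time-window* is the
synchronized set of fixed-length per-channel sequences extracted at one
time point; windows shorter than the configured length at the stream end
are dropped, not padded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sensor_model import SensorStream

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIVITIES",
    "LOCOMOTION_ACTIVITIES",
    "OUTLIER_ACTIVITY",
    "WindowConfig",
    "SubseqConfig",
    "LabeledSegment",
    "TimeWindow",
    "sequence_length",
    "extract_time_windows",
    "extract_training_segments",
    "segments_from_seconds",
]

#: The activity class set Omega.
ACTIVITIES = ("standing", "walking", "stairs_up", "stairs_down", "messing_around")

#: The four trainable locomotion classes; messing_around is a rejection
#: class handled by one-class outlier detection, never trained directly.
LOCOMOTION_ACTIVITIES = ("standing", "walking", "stairs_up", "stairs_down")

OUTLIER_ACTIVITY = "messing_around"


@dataclass
class WindowConfig:
    """Sliding-window geometry for time-window extraction.

    ``window_seconds`` is nominally between 2 s and 3 s.  ``step_samples``
    defaults to a quarter of the window, mirroring the codebook
    pipeline's quarter-sequence step convention.  ``window_samples`` may
    be given directly to override the seconds-based length (the codebook
    geometry yields non-round lengths such as 94 samples).
    """

    window_seconds: float = 2.0
    step_samples: int | None = None
    sample_rate: float = 50.0
    window_samples: int | None = None

    def __post_init__(self) -> None:
        if self.window_samples is None:
            self.window_samples = int(round(self.window_seconds * self.sample_rate))
        if self.window_samples < 2:
            raise ValueError("window must span at least 2 samples")
        if self.step_samples is None:
            self.step_samples = max(1, self.window_samples // 4)
        if self.step_samples < 1:
            raise ValueError("step_samples must be >= 1")


@dataclass
class SubseqConfig:
    """Codebook subsequence geometry.

    ``n_sub`` subsequences of ``w_sub`` samples are taken at a fixed
    stride of ``s_i`` samples inside each sequence; sequences advance by
    a quarter of their contained subsequences.
    """

    n_sub: int = 32
    w_sub: int = 32
    s_i: int = 2

    def __post_init__(self) -> None:
        if self.n_sub < 1 or self.w_sub < 1 or self.s_i < 1:
            raise ValueError("n_sub, w_sub and s_i must be positive")

    @property
    def sequence_step_subseq(self) -> int:
        """Sequence step expressed in subsequences (n_sub / 4)."""
        if self.n_sub % 4 != 0:
            warnings.warn(
                f"n_sub={self.n_sub} not divisible by 4; "
                "falling back to floor(n_sub/4)",
                stacklevel=2,
            )
        return max(1, self.n_sub // 4)

    @property
    def sequence_step_samples(self) -> int:
        return self.sequence_step_subseq * self.s_i

    def sequence_length(self) -> int:
        return sequence_length(self.n_sub, self.s_i, self.w_sub)


@dataclass
class LabeledSegment:
    """Half-open sample range [start, end) carrying one activity label."""

    activity: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if not self.end > self.start:
            raise ValueError("segment end must exceed start")


@dataclass
class TimeWindow:
    """Synchronized per-channel sequences covering one sample range.

    ``data`` has shape ``(n_channels, window_samples)``; all channels
    cover the identical half-open range ``[start, start + w)`` of the
    source streams.
    """

    data: np.ndarray
    channel_names: list[str]
    start: int
    sample_rate: float

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def sequence_length(n_sub: int, s_i: int, w_sub: int) -> int:
    """Sequence length in samples: ``(n_sub - 1) * s_i + w_sub``."""
    if n_sub < 1 or s_i < 1 or w_sub < 1:
        raise ValueError("all arguments must be positive integers")
    return (n_sub - 1) * s_i + w_sub


def _stack_streams(streams: list[SensorStream]) -> tuple[np.ndarray, list[str]]:
    if not streams:
        raise ValueError("no streams given")
    rate = streams[0].sample_rate
    n = streams[0].n_samples
    t0 = streams[0].start_time
    for s in streams[1:]:
        if s.sample_rate != rate:
            raise ValueError("streams must share one sample rate")
        if s.n_samples != n:
            raise ValueError("streams must be equal length (align them first)")
        if abs(s.start_time - t0) * rate > 1e-6:
            raise ValueError("streams must share a start time (align them first)")
    data = np.vstack([s.samples for s in streams])
    names = [c for s in streams for c in s.channel_names]
    if len(set(names)) != len(names):
        raise ValueError("duplicate channel names across streams")
    return data, names


def extract_time_windows(
    streams: list[SensorStream],
    config: WindowConfig,
    start: int = 0,
    stop: int | None = None,
) -> list[TimeWindow]:
    """Extract synchronized time-windows from ``[start, stop)``.

    Returns ``floor((N - w) / step) + 1`` windows (empty when the range
    is shorter than the window).
    """
    data, names = _stack_streams(streams)
    if stop is None:
        stop = data.shape[1]
    start = max(0, start)
    stop = min(data.shape[1], stop)
    w = config.window_samples
    step = config.step_samples
    out = []
    for off in range(start, stop - w + 1, step):
        out.append(
            TimeWindow(
                data[:, off : off + w].copy(),
                names,
                off,
                streams[0].sample_rate,
            )
        )
    return out


def segments_from_seconds(
    labels: list[tuple[float, float, str]], reference: SensorStream
) -> list[LabeledSegment]:
    """Convert second-based label rows to sample segments of a stream.

    The stream may start later than time zero (aligned virtual-sensor
    streams do); boundaries are clamped to the stream's support and
    degenerate segments are dropped.
    """
    rate = reference.sample_rate
    out = []
    for start_s, end_s, activity in labels:
        a = int(np.ceil((start_s - reference.start_time) * rate - 1e-9))
        b = int(np.floor((end_s - reference.start_time) * rate + 1e-9))
        a = max(0, a)
        b = min(reference.n_samples, b)
        if b > a:
            out.append(LabeledSegment(activity, a, b))
    return out


def extract_training_segments(
    streams: list[SensorStream],
    labels: list[LabeledSegment],
    config: WindowConfig,
) -> dict[str, list[TimeWindow]]:
    """Per-class window extraction with one-third boundary overlap.

    Each labeled segment is extended at both ends by ``floor(w / 3)``
    samples into its neighbours (clamped to the recording bounds) before
    plain sliding-window extraction, so transitions between consecutive
    activities are represented in both classes.  The extension stays
    below half a window, which keeps any window from being shared
    verbatim between two classes.
    """
    data_len = streams[0].n_samples
    ordered = sorted(labels, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping labels: {a.activity}[{a.start},{a.end}) and "
                f"{b.activity}[{b.start},{b.end})"
            )
    w = config.window_samples
    ext = w // 3
    out: dict[str, list[TimeWindow]] = {}
    for seg in ordered:
        lo = max(0, seg.start - ext)
        hi = min(data_len, seg.end + ext)
        windows = extract_time_windows(streams, config, start=lo, stop=hi)
        if not windows:
            logger.warning(
                "segment %s[%d,%d) too short for %d-sample windows; skipped",
                seg.activity,
                seg.start,
                seg.end,
                w,
            )
            continue
        out.setdefault(seg.activity, []).extend(windows)
    return out
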