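"""Virtual sensors: artificial channels computed from raw streams.

Virtual sensors take raw accelerometer/gyroscope data and continuously
compute metrics on it, producing additional streams that the rest of a
recognition pipeline treats exactly like hardware channels.  Per-sample
metrics (magnitude, inclination) have zero delay; windowed metrics
(standard deviation, RMS) use a length-``w_virt`` sliding window with
step 1 and attribute each value to the window centre, i.e. a delay of
``(w_virt - 1) / 2`` samples.

The default channel set:

====================  ============  ========  ====
metric                source        windowed  dims
====================  ============  ========  ====
magnitude             accelerometer no        1
standard deviation    accel + gyro  yes       3+3
root mean square      accel + gyro  yes       3+3
inclination           accelerometer no        2
====================  ============  ========  ====

for a total of 15 virtual channels on top of the 6 hardware channels.
Inclination always consumes raw device-frame acceleration, even when
the pipeline otherwise runs on aligned acceleration, because the tilt
information is exactly what alignment removes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sensor_model import SensorStream

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOWED_METRICS",
    "PER_SAMPLE_METRICS",
    "VirtualSensorConfig",
    "magnitude",
    "magnitude_stream",
    "inclination",
    "inclination_stream",
    "windowed_metric",
    "default_virtual_sensors",
    "align_streams",
]

PER_SAMPLE_METRICS = ("magnitude", "inclination")
WINDOWED_METRICS = ("stddev", "variance", "rms")

#: metric -> allowed sources
_ALLOWED = {
    "magnitude": ("accel",),
    "inclination": ("accel",),
    "stddev": ("accel", "gyro"),
    "variance": ("accel", "gyro"),
    "rms": ("accel", "gyro"),
}


@dataclass
class VirtualSensorConfig:
    """Configuration of one virtual sensor.

    ``window_samples`` (w_virt) applies to windowed metrics only and
    must be odd so the attribution delay ``(w_virt - 1) / 2`` is an
    integer number of samples.  The default of 15 samples is 0.3 s at
    50 Hz.
    """

    metric: str
    source: str = "accel"
    window_samples: int = 15
    per_channel: bool = True
    squared_magnitude: bool = False

    def __post_init__(self) -> None:
        if self.metric not in _ALLOWED:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.source not in _ALLOWED[self.metric]:
            raise ValueError(
                f"metric {self.metric!r} is not defined for source {self.source!r}"
            )
        if self.metric in WINDOWED_METRICS:
            if self.window_samples < 3 or self.window_samples % 2 == 0:
                raise ValueError("window_samples must be odd and >= 3")

    @property
    def delay_samples(self) -> int:
        if self.metric in WINDOWED_METRICS:
            return (self.window_samples - 1) // 2
        return 0


def magnitude(sample: np.ndarray, squared: bool = False) -> float:
    """Per-sample magnitude; Euclidean norm by default, ``a^T a`` if
    ``squared``.  Rotation-invariant either way."""
    sample = np.asarray(sample, dtype=float)
    s = float(np.dot(sample, sample))
    return s if squared else float(np.sqrt(s))


def magnitude_stream(stream: SensorStream, squared: bool = False) -> SensorStream:
    s = np.einsum("ct,ct->t", stream.samples, stream.samples)
    if not squared:
        s = np.sqrt(s)
    return SensorStream(
        f"{stream.name}_mag",
        [f"{stream.name}_mag"],
        stream.sample_rate,
        s[None, :],
        stream.start_time,
    )


def inclination(sample: np.ndarray) -> np.ndarray:
    """Device tilt (f_TD, f_LR) from one accelerometer sample, in radians.

    f_TD = atan2(a_y, a_z) is the rotation about the device x-axis
    (top-down), f_LR = atan2(a_x, a_z) about the y-axis (left-right);
    both are in (-pi, pi].  The degenerate all-zero argument pair
    returns 0 by the atan2(0, 0) = 0 convention.
    """
    x, y, z = np.asarray(sample, dtype=float)
    return np.array([np.arctan2(y, z), np.arctan2(x, z)])


def inclination_stream(accel: SensorStream) -> SensorStream:
    x, y, z = accel.samples
    data = np.vstack([np.arctan2(y, z), np.arctan2(x, z)])
    return SensorStream(
        "incl", ["incl_td", "incl_lr"], accel.sample_rate, data, accel.start_time
    )


def windowed_metric(stream: SensorStream, config: VirtualSensorConfig) -> SensorStream:
    """Sliding-window metric stream (stddev / variance / rms, step 1).

    Output length is ``N - w_virt + 1``; each value is attributed to its
    window's centre, expressed through a ``start_time`` shifted by the
    delay.  Population (1/N) denominators are used throughout.
    """
    if config.metric not in WINDOWED_METRICS:
        raise ValueError(f"{config.metric!r} is not a windowed metric")
    w = config.window_samples
    if stream.n_samples < w:
        raise ValueError(
            f"stream of {stream.n_samples} samples shorter than w_virt={w}"
        )
    views = sliding_window_view(stream.samples, w, axis=1)  # (C, N-w+1, w)
    if config.metric == "stddev":
        data = views.std(axis=2)
    elif config.metric == "variance":
        data = views.var(axis=2)
    else:  # rms
        data = np.sqrt(np.mean(views**2, axis=2))
    suffix = {"stddev": "std", "variance": "var", "rms": "rms"}[config.metric]
    return SensorStream(
        f"{stream.name}_{suffix}",
        [f"{c}_{suffix}" for c in stream.channel_names],
        stream.sample_rate,
        data,
        stream.start_time + config.delay_samples / stream.sample_rate,
    )


def default_virtual_sensors(
    accel: SensorStream,
    gyro: SensorStream,
    raw_accel: SensorStream | None = None,
    w_virt: int = 15,
    squared_magnitude: bool = False,
) -> list[SensorStream]:
    """The default 15-channel virtual sensor set.

    ``accel`` is the acceleration the pipeline runs on (raw or aligned);
    ``raw_accel`` is the device-frame acceleration used for inclination
    and defaults to ``accel``.
    """
    if raw_accel is None:
        raw_accel = accel
    std_cfg = VirtualSensorConfig("stddev", "accel", w_virt)
    rms_cfg = VirtualSensorConfig("rms", "accel", w_virt)
    return [
        magnitude_stream(accel, squared=squared_magnitude),
        windowed_metric(accel, std_cfg),
        windowed_metric(gyro, VirtualSensorConfig("stddev", "gyro", w_virt)),
        windowed_metric(accel, rms_cfg),
        windowed_metric(gyro, VirtualSensorConfig("rms", "gyro", w_virt)),
        inclination_stream(raw_accel),
    ]


def align_streams(streams: list[SensorStream]) -> list[SensorStream]:
    """Crop streams to their common time support.

    Streams must share one sample rate; offsets are taken from their
    ``start_time`` (windowed virtual sensors start later and end earlier
    than the raw streams they derive from).  Returns equal-length
    streams with identical start times.
    """
    if not streams:
        return []
    rate = streams[0].sample_rate
    for s in streams:
        if s.sample_rate != rate:
            raise ValueError("streams must share one sample rate")
    base = min(s.start_time for s in streams)
    offsets = [int(round((s.start_time - base) * rate)) for s in streams]
    for s, off in zip(streams, offsets):
        if abs((s.start_time - base) * rate - off) > 1e-6:
            raise ValueError(f"stream {s.name} is not on the common sample grid")
    lo = max(offsets)
    hi = min(off + s.n_samples for s, off in zip(streams, offsets))
    if hi <= lo:
        raise ValueError("streams have no common time support")
    return [s.slice(lo - off, hi - off) for s, off in zip(streams, offsets)]
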