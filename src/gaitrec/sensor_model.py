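"""Sensor data model, coordinate conventions and frame transforms.

A smartphone accelerometer measures, in the device's local coordinate
system, the sum of a static component (the negative gravitational
acceleration rotated into the device frame), the dynamic acceleration
applied by the user, and sensor noise.  The gyroscope measures angular
velocity (rad/s) about the device axes, again composed of a dynamic part
and noise.  Because the device frame rotates with the phone, an
*aligned* representation is often preferable: an earth frame whose
y-axis points up (gravity target ``(0, 1, 0)``) while the two horizontal
axes remain unspecified, and a further two-channel representation
``(vertical, horizontal magnitude)`` that is invariant to rotations
about gravity.

Units: acceleration in m/s^2, angular velocity in rad/s, time in
seconds.  The nominal sample rate is 50 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY",
    "SensorStream",
    "Orientation",
    "AccelDecomposition",
    "Recording",
    "to_earth_frame",
    "to_two_channel",
    "orientation_from_gravity",
    "estimate_orientation",
    "gravity_orientation_series",
    "two_channel_stream",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
]

#: Magnitude of gravitational acceleration in m/s^2.
GRAVITY = 9.81

#: Earth-frame "up" direction; gravity maps measured rest acceleration here.
EARTH_UP = np.array([0.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class SensorStream:
    """A synchronized, uniformly sampled multi-channel signal.

    Parameters
    ----------
    name:
        Identifier of the stream (e.g. ``"acc"`` or ``"acc_std"``).
    channel_names:
        Ordered, unique channel identifiers, one per row of ``samples``.
    sample_rate:
        Sampling frequency in Hz (> 0, nominally 50).
    samples:
        Array of shape ``(n_channels, n_samples)`` in sensor units.
    start_time:
        Time of the first sample in seconds.  Derived streams (windowed
        virtual sensors) carry a later ``start_time`` reflecting their
        attribution delay.
    """

    name: str
    channel_names: list[str]
    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique within a stream")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]

    def slice(self, start: int, stop: int) -> "SensorStream":
        """Return the half-open sample range ``[start, stop)`` as a stream."""
        return SensorStream(
            self.name,
            list(self.channel_names),
            self.sample_rate,
            self.samples[:, start:stop].copy(),
            self.start_time + start / self.sample_rate,
        )


@dataclass
class Orientation:
    """Rotation mapping the earth frame into the device frame (O_E->L)."""

    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        validate_rotation(self.rotation)

    @property
    def inverse_rotation(self) -> np.ndarray:
        """O_L->E, the transpose of the orthonormal O_E->L."""
        return self.rotation.T

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.eye(3))


@dataclass
class AccelDecomposition:
    """Static (gravity), dynamic and noise parts of an acceleration sample."""

    static: np.ndarray
    dynamic: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.static = np.asarray(self.static, dtype=float)
        self.dynamic = np.asarray(self.dynamic, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def total(self) -> np.ndarray:
        return self.static + self.dynamic


@dataclass
class Recording:
    """One continuous dual-sensor recording plus its activity label track.

    ``labels`` is a list of ``(start_s, end_s, activity)`` tuples on the
    recording's time axis.
    """

    accel: SensorStream
    gyro: SensorStream
    labels: list[tuple[float, float, str]] = field(default_factory=list)
    name: str = "recording"


def validate_rotation(rot: np.ndarray, tol: float = 1e-9) -> None:
    """Raise ``ValueError`` unless ``rot`` is a proper rotation matrix."""
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=tol):
        raise ValueError("rotation is not orthonormal")
    if not np.isclose(np.linalg.det(rot), 1.0, atol=tol):
        raise ValueError("rotation determinant is not +1")


# ---------------------------------------------------------------------------
# frame transforms
# ---------------------------------------------------------------------------

def to_earth_frame(sample: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Rotate a device-frame sample into the (underspecified) earth frame.

    Applies ``O_L->E = O_E->L^-1`` to the sample; the vector norm is
    preserved.
    """
    sample = np.asarray(sample, dtype=float)
    return orientation.inverse_rotation @ sample


def to_two_channel(earth_sample: np.ndarray) -> np.ndarray:
    """Collapse an earth-frame sample to (vertical, horizontal magnitude).

    The y-axis is the gravity-aligned vertical; the two horizontal axes
    are reduced to their magnitude, which makes the result invariant to
    rotations about gravity.  Total function: no error cases.
    """
    v = np.asarray(earth_sample, dtype=float)
    return np.array([v[1], np.hypot(v[0], v[2])])


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def orientation_from_gravity(accel_sample: np.ndarray) -> Orientation:
    """Orientation whose earth-up axis maps onto the measured rest direction.

    Given a (mean) accelerometer sample dominated by the static gravity
    component, returns the O_E->L that rotates earth ``(0, 1, 0)`` onto
    the measured acceleration direction.  The yaw about gravity is left
    at zero (the earth frame is underspecified).
    """
    g = np.asarray(accel_sample, dtype=float)
    norm = np.linalg.norm(g)
    if norm == 0:
        raise ValueError("cannot infer orientation from a zero sample")
    g = g / norm
    c = float(np.dot(EARTH_UP, g))
    axis = np.cross(EARTH_UP, g)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return Orientation(np.eye(3))
        # antiparallel: rotate half a turn about x
        return Orientation(_rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi))
    return Orientation(_rotation_about_axis(axis / s, float(np.arctan2(s, c))))


def estimate_orientation(
    accel: SensorStream,
    gyro: SensorStream,
    accel_weight: float = 0.02,
) -> list[Orientation]:
    """Complementary-filter orientation estimate, one per sample.

    The gyroscope is integrated for short-term accuracy and each step is
    nudged toward the accelerometer's gravity direction with a small
    weight (default 0.02 per sample) for long-term stability.  The
    filter is initialised from the first accelerometer sample; on a
    stationary stream the estimated gravity direction converges to the
    measured mean direction.
    """
    if accel.n_samples != gyro.n_samples:
        raise ValueError("accelerometer and gyroscope streams differ in length")
    if accel.sample_rate != gyro.sample_rate:
        raise ValueError("accelerometer and gyroscope sample rates differ")
    dt = 1.0 / accel.sample_rate
    a = accel.samples
    w = gyro.samples

    a0 = a[:, 0]
    if np.linalg.norm(a0) > 1e-9:
        rot = orientation_from_gravity(a0).rotation
    else:
        rot = np.eye(3)

    out: list[Orientation] = []
    for t in range(accel.n_samples):
        if t > 0:
            rv = -w[:, t] * dt
            angle = np.linalg.norm(rv)
            if angle > 1e-12:
                rot = _rotation_about_axis(rv / angle, angle) @ rot
        at = a[:, t]
        norm = np.linalg.norm(at)
        if norm > 1e-9 and accel_weight > 0:
            measured = at / norm
            predicted = rot @ EARTH_UP
            axis = np.cross(predicted, measured)
            s = np.linalg.norm(axis)
            c = float(np.dot(predicted, measured))
            if s > 1e-12:
                corr = accel_weight * float(np.arctan2(s, c))
                rot = _rotation_about_axis(axis / s, corr) @ rot
        if t % 256 == 0 and t > 0:
            # re-orthonormalize accumulated floating point drift
            u, _, vt = np.linalg.svd(rot)
            rot = u @ vt
        out.append(Orientation(rot.copy()))
    if not out:
        raise ValueError("empty streams")
    return out


def gravity_orientation_series(
    accel: SensorStream, window_seconds: float = 2.0
) -> list[Orientation]:
    """Pure-accelerometer orientation from a trailing long-term mean.

    Reference estimator: low-pass the acceleration with a trailing
    moving average of ``window_seconds`` and align earth-up to the
    result.  Large delay; used as a cross-check for the complementary
    filter on quasi-stationary data.
    """
    w = max(1, int(round(window_seconds * accel.sample_rate)))
    cs = np.cumsum(accel.samples, axis=1)
    out = []
    for t in range(accel.n_samples):
        lo = max(0, t - w + 1)
        total = cs[:, t] - (cs[:, lo - 1] if lo > 0 else 0.0)
        out.append(orientation_from_gravity(total / (t - lo + 1)))
    return out


def two_channel_stream(
    accel: SensorStream, orientations: list[Orientation]
) -> SensorStream:
    """Per-sample two-channel (vertical, horizontal) acceleration stream."""
    if len(orientations) != accel.n_samples:
        raise ValueError("one orientation per sample required")
    rots = np.stack([o.inverse_rotation for o in orientations])  # (n, 3, 3)
    earth = np.einsum("tij,jt->it", rots, accel.samples)
    two = np.vstack([earth[1], np.hypot(earth[0], earth[2])])
    return SensorStream(
        f"{accel.name}2",
        [f"{accel.name}2_v", f"{accel.name}2_h"],
        accel.sample_rate,
        two,
        accel.start_time,
    )


# ---------------------------------------------------------------------------
# recording / label CSV dialect
# ---------------------------------------------------------------------------
#
# Recording CSV: one row per sample with columns
#   timestamp_s, sensor ("acc"|"gyro"), x, y, z
# Rows of the two sensors may be interleaved and need not share a time
# grid; the reader aligns both to a common uniform grid by linear
# interpolation.  Label CSV: start_s, end_s, activity.

def read_recording(
    path, sample_rate: float = 50.0, name: str | None = None
) -> Recording:
    """Read a recording CSV, resampling both sensors to ``sample_rate``."""
    df = pd.read_csv(path)
    required = {"timestamp_s", "sensor", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"recording CSV must have columns {sorted(required)}")
    streams = {}
    for sensor in ("acc", "gyro"):
        rows = df[df["sensor"] == sensor].sort_values("timestamp_s")
        if rows.empty:
            raise ValueError(f"recording contains no '{sensor}' rows")
        streams[sensor] = (
            rows["timestamp_s"].to_numpy(),
            rows[["x", "y", "z"]].to_numpy().T,
        )
    t0 = max(t[0] for t, _ in streams.values())
    t1 = min(t[-1] for t, _ in streams.values())
    if t1 <= t0:
        raise ValueError("sensors do not overlap in time")
    grid = np.arange(t0, t1 + 0.5 / sample_rate, 1.0 / sample_rate)
    grid = grid[grid <= t1 + 1e-9]
    out = {}
    for sensor, (t, xyz) in streams.items():
        out[sensor] = np.vstack([np.interp(grid, t, row) for row in xyz])
    rec_name = name if name is not None else str(path)
    return Recording(
        accel=SensorStream(
            "acc", ["acc_x", "acc_y", "acc_z"], sample_rate, out["acc"], grid[0]
        ),
        gyro=SensorStream(
            "gyro", ["gyro_x", "gyro_y", "gyro_z"], sample_rate, out["gyro"], grid[0]
        ),
        name=rec_name,
    )


def write_recording(recording: Recording, path) -> None:
    """Write a recording in the interleaved one-row-per-sample dialect."""
    frames = []
    for sensor, stream in (("acc", recording.accel), ("gyro", recording.gyro)):
        frames.append(
            pd.DataFrame(
                {
                    "timestamp_s": stream.times,
                    "sensor": sensor,
                    "x": stream.samples[0],
                    "y": stream.samples[1],
                    "z": stream.samples[2],
                }
            )
        )
    df = pd.concat(frames).sort_values(
        ["timestamp_s", "sensor"], kind="stable"
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_labels(path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "activity"}
    if not required.issubset(df.columns):
        raise ValueError(f"label CSV must have columns {sorted(required)}")
    return [
        (float(r.start_s), float(r.end_s), str(r.activity))
        for r in df.itertuples()
    ]


def write_labels(labels: list[tuple[float, float, str]], path) -> None:
    pd.DataFrame(labels, columns=["start_s", "end_s", "activity"]).to_csv(
        path, index=False, float_format="%.9g"
    )
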