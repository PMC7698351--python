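"""Synthetic 50 Hz dual-sensor gait recordings for five activity classes.

The generator emulates the qualitative structure of smartphone inertial
recordings in two carry modes:

* **pocket** — the phone rides in a trouser pocket with its y-axis
  along the thigh.  The dominant periodic signal is the thigh's swing,
  an oscillation of the tilt angle about the device x-axis at the *leg*
  frequency (one swing per stride of that leg); the accelerometer sees
  the rotated gravity vector plus a step-synchronous bounce.
* **hand** — the phone is held statically in front of the body with the
  z-axis out of the display, tilted toward the user's face.  Gait
  reaches the sensors mainly as the vertical bounce of the upper body,
  one bounce per step, so the exhibited frequency is roughly double the
  pocket case's leg frequency, and characteristic rotations are weak.

Class signatures:

* ``standing`` — no motion; sensor noise around the gravity-dominated
  rest vector.
* ``walking`` — sinusoid plus harmonics at the mode's fundamental
  frequency.
* ``stairs_up`` — periodic thigh-raise peaks with a *larger* maximal
  inclination and longer peaks than walking (climbing needs high thigh
  lift), at a slightly lower cadence.
* ``stairs_down`` — *sharper and shorter* gyro peaks with reduced
  inclination (toes absorb most of the rotation), slightly faster
  cadence.
* ``messing_around`` — aperiodic bursts with heavy-tailed amplitudes,
  the rejection class.

Peaked waveforms use the periodic bump ``exp(kappa (cos(2 pi f t) - 1))``
whose sharpness grows with ``kappa``.  The device orientation (a static
carry rotation, configurable) is applied to every sample through the
static-acceleration model ``a_static = O_E->L . (0, g, 0)``; the tilt
dynamics additionally rotate the device about its x-axis and drive the
gyroscope as the tilt's time derivative.  All randomness derives from
the configured seed, so recordings regenerate bit-identically.

No biomechanical model is attempted: realism is limited to the
qualitative spectral and shape properties the recognition pipelines
rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sensor_model import (
    GRAVITY,
    Orientation,
    Recording,
    SensorStream,
    write_labels,
    write_recording,
)
from .windowing import ACTIVITIES

__all__ = [
    "SimConfig",
    "simulate_recording",
    "make_benchmark_suite",
    "BenchmarkSuite",
    "default_orientation",
]

#: Default fundamental frequencies (Hz): pocket = leg (stride) frequency,
#: hand = step frequency, roughly double the pocket value.
DEFAULT_FREQUENCY = {"pocket": 0.9, "hand": 1.8}


@dataclass
class SimConfig:
    """Study conditions of one simulated subject/recording.

    ``step_frequency`` is the mode's fundamental in Hz (pocket: leg
    swings per second, hand: steps per second); ``None`` selects the
    mode default.  ``thigh_inclination_amplitude`` is the walking thigh
    swing half-range in radians; stair ascent doubles it, descent
    reduces it.  ``descent_peak_sharpness`` is the bump sharpness
    ``kappa`` for stairs-down (larger = sharper, shorter peaks).
    Noise levels are typical smartphone MEMS magnitudes.
    """

    carry_mode: str = "pocket"
    step_frequency: float | None = None
    accel_amplitude: float = 2.0  # m/s^2 dynamic bounce scale
    gyro_amplitude: float = 1.0  # rad/s scale of non-tilt rotation noise
    thigh_inclination_amplitude: float = 0.35  # rad
    descent_peak_sharpness: float = 8.0
    noise_sd_accel: float = 0.25  # m/s^2
    noise_sd_gyro: float = 0.03  # rad/s
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: Orientation | None = None
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carry_mode not in ("pocket", "hand"):
            raise ValueError("carry_mode must be 'pocket' or 'hand'")
        if self.step_frequency is None:
            self.step_frequency = DEFAULT_FREQUENCY[self.carry_mode]
        if not 0.5 <= self.step_frequency <= 3.0:
            raise ValueError("step_frequency must be in [0.5, 3] Hz")
        for name in (
            "accel_amplitude",
            "gyro_amplitude",
            "thigh_inclination_amplitude",
            "descent_peak_sharpness",
            "noise_sd_accel",
            "noise_sd_gyro",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.accel_bias = np.asarray(self.accel_bias, dtype=float)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)


def default_orientation(carry_mode: str) -> Orientation:
    """Rest orientation convention per carry mode.

    Pocket: device y along the (vertical) thigh, so O_E->L is the
    identity at rest.  Hand: display toward the user's face — the
    device is pitched back about its x-axis by 40 degrees from the
    upright pose, z pointing up-and-backward out of the screen.
    """
    if carry_mode == "pocket":
        return Orientation(np.eye(3))
    angle = np.deg2rad(40.0)
    c, s = np.cos(angle), np.sin(angle)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    return Orientation(rx)


def _periodic_bump(phase: np.ndarray, kappa: float) -> np.ndarray:
    """Unit-peak periodic bump train; larger kappa = sharper bumps."""
    return np.exp(kappa * (np.cos(phase) - 1.0))


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.hanning(min(max(3, width), x.shape[0]))
    kernel /= kernel.sum()
    return np.convolve(x, kernel, mode="same")


def _activity_tracks(
    activity: str, n: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tilt angle theta(t), earth-frame dynamic accel (3, n), extra gyro.

    ``theta`` is the device tilt about its x-axis; the gyroscope x-axis
    signal is derived from it by differentiation.  ``extra_gyro`` holds
    aperiodic rotation (messing bursts, hand-carry wobble).
    """
    fs = cfg.sample_rate
    t = np.arange(n) / fs
    f = cfg.step_frequency
    amp = cfg.accel_amplitude
    incl = cfg.thigh_inclination_amplitude
    theta = np.zeros(n)
    dyn = np.zeros((3, n))
    extra_gyro = np.zeros((3, n))
    pocket = cfg.carry_mode == "pocket"
    phase = 2.0 * np.pi * rng.uniform()

    if activity == "standing":
        pass
    elif activity == "walking":
        if pocket:
            theta = incl * np.sin(2 * np.pi * f * t + phase)
            # phone-side leg dominates: fundamental at the leg frequency
            dyn[1] = amp * (
                np.sin(2 * np.pi * f * t + phase + 0.7)
                + 0.45 * np.sin(4 * np.pi * f * t + phase + 1.9)
            )
            dyn[0] = 0.25 * amp * np.sin(2 * np.pi * f * t + phase + 0.3)
            dyn[2] = 0.18 * amp * np.sin(4 * np.pi * f * t + phase + 2.4)
        else:
            # upper-body bounce once per step; little characteristic rotation
            theta = 0.12 * incl * np.sin(2 * np.pi * f * t + phase)
            dyn[1] = amp * (
                np.sin(2 * np.pi * f * t + phase)
                + 0.35 * np.sin(4 * np.pi * f * t + phase + 1.1)
            )
            dyn[0] = 0.2 * amp * np.sin(2 * np.pi * f * t + phase + 0.8)
            dyn[2] = 0.15 * amp * np.sin(2 * np.pi * f * t + phase + 2.0)
    elif activity == "stairs_up":
        fu = 0.8 * f
        ph = 2 * np.pi * fu * t + phase
        if pocket:
            # long, high thigh-raise peaks: larger inclination integral
            theta = 2.0 * incl * _periodic_bump(ph, 2.0)
            dyn[1] = 1.1 * amp * (_periodic_bump(2 * ph + 0.5, 3.0) - 0.35)
            dyn[0] = 0.2 * amp * np.sin(ph + 0.4)
            dyn[2] = 0.15 * amp * np.sin(2 * ph + 1.3)
        else:
            theta = 0.35 * incl * _periodic_bump(ph, 2.0)
            dyn[1] = 0.9 * amp * (
                np.sin(ph) + 0.25 * np.sin(2 * ph + 0.9)
            )
            # slower, heavier vertical lift component
            dyn[1] += 0.5 * amp * _periodic_bump(ph + 1.2, 1.5)
            dyn[0] = 0.25 * amp * np.sin(ph + 1.7)
            dyn[2] = 0.2 * amp * np.sin(ph + 0.2)
    elif activity == "stairs_down":
        fd = 1.15 * f
        ph = 2 * np.pi * fd * t + phase
        kappa = cfg.descent_peak_sharpness
        if pocket:
            # sharp, short peaks with reduced maximal inclination
            theta = 0.6 * incl * _periodic_bump(ph, kappa)
            dyn[1] = 1.2 * amp * (_periodic_bump(ph + 0.6, kappa) - 0.2)
            dyn[0] = 0.2 * amp * np.sin(ph + 2.1)
            dyn[2] = 0.15 * amp * np.sin(2 * ph + 0.9)
        else:
            theta = 0.1 * incl * _periodic_bump(ph, kappa)
            dyn[1] = 1.1 * amp * (_periodic_bump(ph, kappa) - 0.25)
            dyn[0] = 0.25 * amp * np.sin(ph + 0.5)
            dyn[2] = 0.2 * amp * np.sin(ph + 1.4)
            extra_gyro[0] = 0.25 * cfg.gyro_amplitude * (
                _periodic_bump(ph + 0.3, kappa) - 0.2
            )
    elif activity == "messing_around":
        # aperiodic bursts: heavy-tailed random walks gated on and off
        width = int(round(0.12 * fs))
        gate = np.zeros(n)
        pos = 0
        while pos < n:
            burst = int(rng.uniform(0.4, 2.0) * fs)
            quiet = int(rng.uniform(0.2, 1.2) * fs)
            gate[pos : pos + burst] = 1.0
            pos += burst + quiet
        gate = _smooth(gate, width)
        heavy = rng.standard_t(2.0, size=(4, n)).clip(-12, 12)
        for i in range(3):
            dyn[i] = 2.5 * amp * gate * _smooth(heavy[i], width)
        theta = np.cumsum(gate * rng.normal(0.0, 0.04, n))
        theta = theta - _smooth(theta, int(4 * fs))  # keep the walk bounded
        extra_gyro[1] = 1.5 * cfg.gyro_amplitude * gate * _smooth(heavy[3], width)
        extra_gyro[2] = 1.5 * cfg.gyro_amplitude * gate * _smooth(
            rng.standard_t(2.0, size=n).clip(-12, 12), width
        )
    else:
        raise ValueError(f"unknown activity {activity!r}")
    return theta, dyn, extra_gyro


def simulate_recording(
    script: list[tuple[str, float]], config: SimConfig
) -> Recording:
    """Simulate one labelled recording from an (activity, duration) script.

    The measured acceleration is
    ``a = O_E->L(t) . ((0, g, 0) + a_dynamic)`` plus bias and Gaussian
    noise, where ``O_E->L(t) = R_x(-theta(t)) . B^T`` combines the
    static carry orientation ``B`` with the activity's tilt dynamics;
    the gyroscope measures ``(d theta / dt, 0, 0)`` plus aperiodic
    components, bias and noise.  Deterministic given the seed.
    """
    if not script:
        raise ValueError("script must contain at least one activity")
    for activity, duration in script:
        if activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {activity!r}")
        if not duration > 0:
            raise ValueError("durations must be > 0")
    cfg = config
    fs = cfg.sample_rate
    rng = np.random.default_rng(cfg.seed)
    base = (
        cfg.orientation
        if cfg.orientation is not None
        else default_orientation(cfg.carry_mode)
    )
    b_t = base.rotation  # O_E->L of the static carry pose

    thetas, dyns, extras, labels = [], [], [], []
    t_cursor = 0.0
    for activity, duration in script:
        n = int(round(duration * fs))
        th, dyn, extra = _activity_tracks(activity, n, cfg, rng)
        thetas.append(th)
        dyns.append(dyn)
        extras.append(extra)
        labels.append((t_cursor, t_cursor + n / fs, activity))
        t_cursor += n / fs

    theta = np.concatenate(thetas)
    dyn = np.concatenate(dyns, axis=1)
    extra = np.concatenate(extras, axis=1)
    n = theta.shape[0]

    a_earth = dyn + np.array([0.0, GRAVITY, 0.0])[:, None]
    w = b_t @ a_earth  # static carry rotation
    c, s = np.cos(theta), np.sin(theta)
    accel = np.empty((3, n))
    accel[0] = w[0]
    accel[1] = c * w[1] + s * w[2]  # R_x(-theta) applied row-wise
    accel[2] = -s * w[1] + c * w[2]

    gyro = extra.copy()
    gyro[0] += np.gradient(theta) * fs

    accel += cfg.accel_bias[:, None] + rng.normal(0.0, cfg.noise_sd_accel, (3, n))
    gyro += cfg.gyro_bias[:, None] + rng.normal(0.0, cfg.noise_sd_gyro, (3, n))

    return Recording(
        accel=SensorStream("acc", ["acc_x", "acc_y", "acc_z"], fs, accel),
        gyro=SensorStream("gyro", ["gyro_x", "gyro_y", "gyro_z"], fs, gyro),
        labels=labels,
        name=f"{cfg.carry_mode}_seed{cfg.seed}",
    )


@dataclass
class BenchmarkSuite:
    """Fixed-seed simulated benchmark: recordings per carry mode."""

    recordings: dict[str, list[Recording]]
    seed: int

    def write(self, directory) -> None:
        """Emit recording + label CSVs, one subdirectory per carry mode."""
        root = Path(directory)
        for mode, recs in self.recordings.items():
            sub = root / mode
            sub.mkdir(parents=True, exist_ok=True)
            for rec in recs:
                write_recording(rec, sub / f"{rec.name}.csv")
                write_labels(rec.labels, sub / f"{rec.name}.labels.csv")


def make_benchmark_suite(
    seed: int,
    n_subjects: int = 8,
    seconds_per_activity: float = 60.0,
    modes: tuple[str, ...] = ("pocket", "hand"),
) -> BenchmarkSuite:
    """Simulate the benchmark suite: per carry mode, ``n_subjects``
    recordings of all five activities with subject-level jitter.

    Each subject gets a fundamental frequency jittered by +/-20%,
    amplitudes by +/-30%, a random carry yaw about gravity, a small
    tilt perturbation, per-channel sensor biases and a shuffled
    activity order.  Bit-identical regeneration from the same seed.
    """
    rng = np.random.default_rng(seed)
    recordings: dict[str, list[Recording]] = {}
    for mode in modes:
        recs = []
        base = default_orientation(mode).rotation
        f0 = DEFAULT_FREQUENCY[mode]
        for subject in range(n_subjects):
            freq = f0 * (1.0 + rng.uniform(-0.2, 0.2))
            a_scale = 1.0 + rng.uniform(-0.3, 0.3)
            g_scale = 1.0 + rng.uniform(-0.3, 0.3)
            yaw = rng.uniform(-np.pi, np.pi)
            cy, sy = np.cos(yaw), np.sin(yaw)
            ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
            tilt = rng.normal(0.0, np.deg2rad(5.0))
            ct, st = np.cos(tilt), np.sin(tilt)
            rz = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
            orientation = Orientation(rz @ base @ ry)
            cfg = SimConfig(
                carry_mode=mode,
                step_frequency=freq,
                accel_amplitude=2.0 * a_scale,
                gyro_amplitude=1.0 * g_scale,
                thigh_inclination_amplitude=0.35 * a_scale,
                accel_bias=rng.normal(0.0, 0.05, 3),
                gyro_bias=rng.normal(0.0, 0.005, 3),
                orientation=orientation,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            order = rng.permutation(len(ACTIVITIES))
            script = [(ACTIVITIES[i], seconds_per_activity) for i in order]
            rec = simulate_recording(script, cfg)
            rec = replace(rec, name=f"{mode}_subject{subject}")
            recs.append(rec)
        recordings[mode] = recs
    return BenchmarkSuite(recordings=recordings, seed=seed)
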