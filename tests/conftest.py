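import numpy as np
import pytest

from gaitrec.sensor_model import SensorStream
from gaitrec.synthetic_data import SimConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def make_stream():
    def _make(samples, rate=50.0, name="acc", start=0.0, channels=None):
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if channels is None:
            channels = [f"{name}_{ax}" for ax in "xyz"[: samples.shape[0]]] \
                if samples.shape[0] <= 3 else \
                [f"{name}_{i}" for i in range(samples.shape[0])]
        return SensorStream(name, channels, rate, samples, start)

    return _make


@pytest.fixture
def quiet_pocket_recording():
    """Noise-free pocket recording with one segment per activity."""
    cfg = SimConfig(
        carry_mode="pocket", noise_sd_accel=0.0, noise_sd_gyro=0.0, seed=5
    )
    script = [(a, 12.0) for a in
              ("standing", "walking", "stairs_up", "stairs_down", "messing_around")]
    return simulate_recording(script, cfg)
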