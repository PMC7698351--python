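"""Statistical feature battery: MFCC, AR, entropy, correlation, layout."""

import numpy as np
import pytest

from gaitrec.statfeat_pipeline import (
    ArConfig,
    MfccConfig,
    StatFeatConfig,
    ar_coefficients,
    assemble_features,
    build_layout,
    correlation,
    entropy,
    mfcc,
    mfcc_filterbank,
    percentile75,
    reduce_features,
    sma,
)
from gaitrec.windowing import TimeWindow


class TestMfcc:
    def test_output_dimension_is_n_mel(self, rng):
        for n_mel in (3, 5, 10, 15):
            out = mfcc(rng.normal(size=125), 50.0, MfccConfig(n_mel=n_mel))
            assert out.shape == (n_mel,)

    def test_eight_channels_at_15_filters_give_120_dims(self, rng):
        cfg = MfccConfig(n_mel=15)
        blocks = [mfcc(rng.normal(size=100), 50.0, cfg) for _ in range(8)]
        assert np.concatenate(blocks).shape == (120,)

    def test_tone_at_filter_centre_maximises_that_filter(self):
        fs, n = 50.0, 500
        cfg = MfccConfig(n_mel=8, psi=1.6)
        fb = mfcc_filterbank(n // 2 + 1, fs, cfg)
        freqs = np.linspace(0, fs / 2, n // 2 + 1)
        target = 4  # a mid-bank filter
        centre = freqs[np.argmax(fb[target])]
        t = np.arange(n) / fs
        tone = np.sin(2 * np.pi * centre * t)
        spec = np.abs(np.fft.rfft(tone)) ** 2
        energies = np.log(np.maximum(fb @ spec, 1e-12))
        assert np.argmax(energies) == target

    def test_filterbank_tiles_zero_to_nyquist_with_growing_bandwidth(self):
        cfg = MfccConfig(n_mel=6, psi=1.6)
        fb = mfcc_filterbank(201, 50.0, cfg)
        freqs = np.linspace(0, 25.0, 201)
        widths = [np.ptp(freqs[fb[i] > 0]) for i in range(6)]
        assert all(b > a for a, b in zip(widths, widths[1:]))
        covered = fb.sum(axis=0) > 0
        assert covered[1:-1].all()

    def test_all_zero_sequence_is_finite(self):
        out = mfcc(np.zeros(100), 50.0, MfccConfig())
        assert np.all(np.isfinite(out))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            mfcc(np.zeros(8), 50.0, MfccConfig())

    def test_shift_tolerance_of_periodic_signal(self):
        fs, n = 50.0, 125
        t = np.arange(n) / fs
        cfg = MfccConfig(n_mel=10, psi=1.6)
        a = mfcc(np.sin(2 * np.pi * 2.0 * t), fs, cfg)
        b = mfcc(np.sin(2 * np.pi * 2.0 * (t + 0.1)), fs, cfg)
        rel = np.linalg.norm(a - b) / np.linalg.norm(a)
        assert rel < 0.05

    def test_normalized_and_unnormalized_banks_differ_only_in_scale(self):
        fb_u = mfcc_filterbank(101, 50.0, MfccConfig(n_mel=5, normalized=False))
        fb_n = mfcc_filterbank(101, 50.0, MfccConfig(n_mel=5, normalized=True))
        for u, n_ in zip(fb_u, fb_n):
            mask = u > 0
            ratio = n_[mask] / u[mask]
            assert np.allclose(ratio, ratio[0])


class TestArCoefficients:
    def test_output_length(self, rng):
        out = ar_coefficients(rng.normal(size=100), ArConfig(order=7))
        assert out.shape == (7,)

    @pytest.mark.parametrize("method", ["yule_walker", "burg"])
    def test_recovers_ar2_parameters(self, method):
        rng = np.random.default_rng(7)
        phi1, phi2 = 0.6, -0.3
        n = 10_000
        x = np.zeros(n)
        eps = rng.normal(size=n)
        for t in range(2, n):
            x[t] = phi1 * x[t - 1] + phi2 * x[t - 2] + eps[t]
        est = ar_coefficients(x, ArConfig(order=2, method=method))
        assert est[0] == pytest.approx(phi1, abs=0.05)
        assert est[1] == pytest.approx(phi2, abs=0.05)

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(3)
        w = 4000
        est = ar_coefficients(rng.normal(size=w), ArConfig(order=5))
        assert np.all(np.abs(est) < 3 / np.sqrt(w))

    def test_constant_sequence_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = ar_coefficients(np.full(50, 3.3), ArConfig(order=4))
        assert np.allclose(out, 0.0)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ar_coefficients(np.zeros(4), ArConfig(order=5))


class TestScalarFeatures:
    def test_sma_examples_and_oracle(self, rng):
        assert sma(np.zeros((3, 10))) == 0.0
        assert sma(np.ones((3, 10))) == pytest.approx(3.0)
        ch = rng.normal(size=(3, 17))
        manual = sum(
            abs(ch[c, t]) for c in range(3) for t in range(17)
        ) / 17
        assert sma(ch) == pytest.approx(manual, abs=1e-12)

    def test_entropy_constant_is_zero(self):
        assert entropy(np.full(100, 1.7)) == 0.0

    def test_entropy_uniform_256_values_is_8_bits(self):
        x = np.arange(256).astype(float)
        assert entropy(x) == pytest.approx(8.0, abs=1e-9)

    def test_entropy_matches_histogram_oracle(self, rng):
        x = rng.normal(size=500)
        counts, _ = np.histogram(x, bins=256, range=(x.min(), x.max()))
        p = counts[counts > 0] / 500
        assert entropy(x) == pytest.approx(-(p * np.log2(p)).sum(), abs=1e-12)

    def test_entropy_bounds(self, rng):
        for _ in range(20):
            assert 0.0 <= entropy(rng.normal(size=64)) <= 8.0

    def test_correlation_dims_and_self_pair(self, rng):
        x = rng.normal(size=30)
        ch = np.vstack([x, x, rng.normal(size=30)])
        out = correlation(ch)
        assert out.shape == (3,)
        assert out[0] == pytest.approx(1.0)

    def test_correlation_matches_textbook_formula(self, rng):
        a, b = rng.normal(size=(2, 50))
        manual = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert correlation(np.vstack([a, b]))[0] == pytest.approx(manual, abs=1e-12)

    def test_correlation_zero_variance_warns(self, rng):
        ch = np.vstack([np.ones(20), rng.normal(size=20)])
        with pytest.warns(UserWarning):
            out = correlation(ch)
        assert out[0] == 0.0

    def test_correlations_bounded(self, rng):
        for _ in range(50):
            out = correlation(rng.normal(size=(3, 25)))
            assert np.all(np.abs(out) <= 1.0 + 1e-12)

    def test_percentile75_interpolation_rule(self):
        assert percentile75(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(3.25)
        assert percentile75(np.full(9, 2.0)) == 2.0

    def test_percentile75_matches_sorted_interpolation_oracle(self, rng):
        x = rng.normal(size=37)
        s = np.sort(x)
        r = 0.75 * (37 - 1)
        lo, frac = int(np.floor(r)), r - int(np.floor(r))
        manual = s[lo] + frac * (s[lo + 1] - s[lo])
        assert percentile75(x) == pytest.approx(manual, abs=1e-12)


def _window(rng, n=125, two_channel=False, zero=False):
    names = ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]
    rows = 6
    if two_channel:
        names += ["acc2_v", "acc2_h"]
        rows = 8
    data = np.zeros((rows, n)) if zero else rng.normal(size=(rows, n))
    return TimeWindow(data, names, 0, 50.0)


class TestAssembleFeatures:
    def test_raw_layout_dimension(self, rng):
        cfg = StatFeatConfig()
        vec = assemble_features(_window(rng), cfg)
        layout = build_layout(cfg)
        # n_mel=10, q=5 raw: 8 * 10 mfcc + 15 ar + rest
        assert layout.total_dims == 126
        assert vec.shape == (126,)

    def test_two_channel_layout_shrinks_accel_rows(self, rng):
        cfg = StatFeatConfig(accel_convention="two_channel")
        layout = build_layout(cfg)
        vec = assemble_features(_window(rng, two_channel=True), cfg)
        assert vec.shape == (layout.total_dims,)
        raw = build_layout(StatFeatConfig())
        mfcc_raw = [r for r in raw.rows if r[0] == "mfcc" and r[1] == "accel"][0]
        mfcc_two = [r for r in layout.rows if r[0] == "mfcc" and r[1] == "accel"][0]
        assert mfcc_raw[2] == 30 and mfcc_two[2] == 20
        corr_two = [r for r in layout.rows if r[0] == "correlation" and r[1] == "accel"][0]
        assert corr_two[2] == 1

    def test_all_zero_window_is_finite(self, rng):
        with pytest.warns(UserWarning):
            vec = assemble_features(_window(rng, zero=True), StatFeatConfig())
        assert np.all(np.isfinite(vec))

    def test_missing_channel_error_names_it(self, rng):
        w = TimeWindow(rng.normal(size=(3, 125)),
                       ["acc_x", "acc_y", "acc_z"], 0, 50.0)
        with pytest.raises(KeyError, match="gyro_x"):
            assemble_features(w, StatFeatConfig())

    def test_gyro_integration_is_rectangular_sum(self, rng):
        cfg = StatFeatConfig()
        w = _window(rng)
        vec = assemble_features(w, cfg)
        offset = 0
        for feature, source, dims in build_layout(cfg).rows:
            if feature == "integration":
                block = vec[offset : offset + dims]
                break
            offset += dims
        gyro = np.vstack([w.channel(f"gyro_{ax}") for ax in "xyz"])
        assert np.allclose(block, gyro.sum(axis=1) / 50.0, atol=1e-12)


class TestReduceFeatures:
    def test_single_transform_on_concatenated_features(self, rng):
        by_class = {
            "walking": rng.normal(size=(40, 30)) + 2,
            "standing": rng.normal(size=(40, 30)) - 2,
        }
        with pytest.warns(UserWarning, match="capping"):
            transform, reduced = reduce_features(by_class, method="lda", d=5)
        assert transform.d == 1  # capped at n_classes - 1
        assert reduced["walking"].shape == (40, 1)

    def test_pca_reduction_dimension(self, rng):
        by_class = {"a": rng.normal(size=(50, 20))}
        transform, reduced = reduce_features(by_class, method="pca", d=4)
        assert reduced["a"].shape == (50, 4)
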