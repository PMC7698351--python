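"""Codebook learning, soft assignment and histogram features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaitrec.codebook_pipeline import (
    Codebook,
    codebook_from_json,
    codebook_to_json,
    soft_assign,
    soft_assign_batch,
    stream_features,
    train_codebook,
    window_histogram,
)
from gaitrec.sensor_model import SensorStream
from gaitrec.windowing import SubseqConfig, TimeWindow


class TestTrainCodebook:
    def test_repeated_distinct_inputs_become_codewords(self, rng):
        shapes = rng.normal(size=(3, 16)) * 5
        subs = np.repeat(shapes, 20, axis=0)
        cb = train_codebook(subs, size=3, sigma=0.25, seed=0)
        found = {tuple(np.round(c, 6)) for c in cb.codewords}
        expected = {tuple(np.round(s, 6)) for s in shapes}
        assert found == expected

    def test_planted_shape_families_recovered(self, rng):
        t = np.linspace(0, 2 * np.pi, 24)
        fam_a = np.sin(t) + rng.normal(0, 0.05, size=(50, 24))
        fam_b = np.sign(np.sin(t)) + rng.normal(0, 0.05, size=(50, 24))
        cb = train_codebook(np.vstack([fam_a, fam_b]), size=2, sigma=0.25, seed=1)
        means = np.array([fam_a.mean(axis=0), fam_b.mean(axis=0)])
        for m in means:
            dists = np.linalg.norm(cb.codewords - m, axis=1)
            assert dists.min() < 0.2

    def test_deterministic_given_seed(self, rng):
        subs = rng.normal(size=(100, 8))
        a = train_codebook(subs, size=4, sigma=0.5, seed=7)
        b = train_codebook(subs, size=4, sigma=0.5, seed=7)
        assert np.array_equal(a.codewords, b.codewords)

    def test_fewer_subsequences_than_codewords_rejected(self, rng):
        with pytest.raises(ValueError):
            train_codebook(rng.normal(size=(3, 8)), size=4, sigma=0.5)


class TestSoftAssign:
    def test_delta_assignment_for_matching_codeword(self):
        cb = Codebook(np.array([[0.0, 0.0], [50.0, 50.0], [-80.0, 20.0]]), sigma=0.1)
        out = soft_assign(np.array([0.0, 0.0]), cb)
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    def test_equidistant_codewords_split_evenly(self):
        cb = Codebook(np.array([[1.0, 0.0], [-1.0, 0.0]]), sigma=0.7)
        assert np.allclose(soft_assign(np.array([0.0, 0.5]), cb), [0.5, 0.5])

    def test_matches_gaussian_kernel_oracle(self, rng):
        cb = Codebook(rng.normal(size=(5, 6)), sigma=0.8)
        for _ in range(20):
            x = rng.normal(size=6)
            d2 = np.array(
                [sum((x[k] - c[k]) ** 2 for k in range(6)) for c in cb.codewords]
            )
            weights = np.exp(-d2 / (2 * 0.8**2))
            assert np.allclose(soft_assign(x, cb), weights / weights.sum(), atol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        x=arrays(np.float64, 6, elements=st.floats(-50, 50)),
        sigma=st.floats(0.05, 10.0),
    )
    def test_always_a_simplex_vector(self, x, sigma):
        cb = Codebook(np.linspace(-40, 40, 4 * 6).reshape(4, 6), sigma=sigma)
        out = soft_assign(x, cb)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_large_sigma_tends_to_uniform(self, rng):
        cb = Codebook(rng.normal(size=(4, 5)), sigma=1e6)
        out = soft_assign(rng.normal(size=5), cb)
        assert np.allclose(out, 0.25, atol=1e-6)

    def test_small_sigma_tends_to_one_hot(self, rng):
        cb = Codebook(rng.normal(size=(4, 5)) * 3, sigma=1e-3)
        x = cb.codewords[2] + 0.01
        out = soft_assign(x, cb)
        assert out[2] == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self, rng):
        cb = Codebook(rng.normal(size=(3, 8)), sigma=0.5)
        with pytest.raises(ValueError):
            soft_assign(np.zeros(9), cb)


def _window_from(data, names):
    return TimeWindow(np.asarray(data, float), names, 0, 50.0)


class TestWindowHistogram:
    def _setup(self, rng, cfg, strategy="independent"):
        acc = rng.normal(size=(3, cfg.sequence_length()))
        gyro = rng.normal(size=(3, cfg.sequence_length()))
        window = _window_from(
            np.vstack([acc, gyro]),
            ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"],
        )
        w = cfg.w_sub if strategy == "independent" else 3 * cfg.w_sub
        codebooks = {
            "acc": Codebook(rng.normal(size=(4, w)), sigma=0.5, sensor="acc"),
            "gyro": Codebook(rng.normal(size=(4, w)), sigma=0.5, sensor="gyro"),
        }
        return window, codebooks

    def test_independent_gives_three_histograms_per_sensor(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=10, s_i=2)
        window, codebooks = self._setup(rng, cfg)
        out = window_histogram(window, codebooks, cfg, strategy="independent")
        assert len(out) == 6  # 3 per 3-channel sensor
        for h in out:
            assert h.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(h >= 0)

    def test_append_gives_one_histogram_per_sensor(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=10, s_i=2)
        window, codebooks = self._setup(rng, cfg, strategy="append")
        out = window_histogram(window, codebooks, cfg, strategy="append")
        assert len(out) == 2
        for h in out:
            assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_histogram_is_mean_of_subsequence_assignments(self, rng):
        cfg = SubseqConfig(n_sub=4, w_sub=6, s_i=3)
        window, codebooks = self._setup(rng, cfg)
        out = window_histogram(window, codebooks, cfg)
        seq = window.data[0]
        manual = np.mean(
            [
                soft_assign(seq[i * 3 : i * 3 + 6], codebooks["acc"])
                for i in range(4)
            ],
            axis=0,
        )
        assert np.allclose(out[0], manual, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=10, s_i=2)
        window, codebooks = self._setup(rng, cfg)
        with pytest.raises(ValueError):
            window_histogram(window, codebooks, cfg, strategy="append")

    def test_wrong_window_width_rejected(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=10, s_i=2)
        _, codebooks = self._setup(rng, cfg)
        bad = _window_from(
            rng.normal(size=(6, cfg.sequence_length() + 1)),
            ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"],
        )
        with pytest.raises(ValueError):
            window_histogram(bad, codebooks, cfg)


class TestStreamFeatures:
    def _streams(self, rng, n):
        return [
            SensorStream("acc", ["acc_x", "acc_y", "acc_z"], 50.0,
                         rng.normal(size=(3, n))),
            SensorStream("gyro", ["gyro_x", "gyro_y", "gyro_z"], 50.0,
                         rng.normal(size=(3, n))),
        ]

    def _codebooks(self, rng, w):
        return {
            "acc": Codebook(rng.normal(size=(5, w)), sigma=0.4, sensor="acc"),
            "gyro": Codebook(rng.normal(size=(5, w)), sigma=0.4, sensor="gyro"),
        }

    def test_default_geometry_steps_16_samples(self, rng):
        cfg = SubseqConfig()  # n_sub=32, s_i=2 -> step 8 * 2 = 16
        streams = self._streams(rng, 300)
        starts, feats = stream_features(streams, self._codebooks(rng, 32), cfg)
        assert np.array_equal(starts[:3], [0, 16, 32])
        assert feats.shape[0] == starts.shape[0]

    def test_cached_equals_naive_recomputation(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=12, s_i=2)
        streams = self._streams(rng, 120)
        codebooks = self._codebooks(rng, 12)
        starts, feats = stream_features(streams, codebooks, cfg)
        names = [c for s in streams for c in s.channel_names]
        data = np.vstack([s.samples for s in streams])
        for p, vec in zip(starts, feats):
            window = _window_from(data[:, p : p + cfg.sequence_length()], names)
            naive = np.concatenate(window_histogram(window, codebooks, cfg))
            assert np.allclose(vec, naive, atol=1e-12)

    def test_exact_length_stream_gives_single_feature(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=12, s_i=2)
        streams = self._streams(rng, cfg.sequence_length())
        starts, feats = stream_features(streams, self._codebooks(rng, 12), cfg)
        assert len(starts) == 1
        assert feats.shape == (1, 2 * 3 * 5)

    def test_too_short_stream_rejected(self, rng):
        cfg = SubseqConfig(n_sub=8, w_sub=12, s_i=2)
        with pytest.raises(ValueError):
            stream_features(
                self._streams(rng, 10), self._codebooks(rng, 12), cfg
            )


class TestSerialization:
    def test_json_round_trip(self, rng):
        cb = Codebook(rng.normal(size=(4, 16)), sigma=0.25, sensor="acc", seed=3)
        back = codebook_from_json(codebook_to_json(cb, "abc"))
        assert np.allclose(back.codewords, cb.codewords)
        assert back.sigma == cb.sigma
        assert back.sensor == "acc"
        assert back.seed == 3

    def test_sigma_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            Codebook(rng.normal(size=(2, 4)), sigma=0.0)
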