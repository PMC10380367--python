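"""Segmentation, split arithmetic, and SNR-exact mixing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcenv.corpus import (
    DEFAULT_SNRS_DB,
    Segment,
    ZeroEnergyError,
    build_noisy_set,
    make_split,
    mix_at_snr,
    mixing_gain,
    segment_waveform,
)
from tcenv.io_wav import Waveform
from tcenv.metrics import snr_db


def _wave(seconds: float, sr: int = 32000, seed: int = 0) -> Waveform:
    rng = np.random.default_rng(seed)
    return Waveform(rng.normal(size=int(round(seconds * sr))) * 0.1, sr)


class TestSegmentation:
    def test_ten_second_recording_gives_four_segments(self):
        segs = segment_waveform(_wave(10.0), 3.0, 2.0)
        assert [s.offset for s in segs] == [0, 64000, 128000, 192000]
        assert all(len(s) == 96000 for s in segs)

    def test_exact_window_gives_one_segment(self):
        assert len(segment_waveform(_wave(3.0), 3.0, 2.0)) == 1

    def test_below_one_window_gives_none(self):
        assert segment_waveform(_wave(2.9), 3.0, 2.0) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 2000), w=st.integers(1, 300), s=st.integers(1, 300))
    def test_count_matches_floor_arithmetic(self, n, w, s):
        wave = Waveform(np.ones(n), 100)
        segs = segment_waveform(wave, w / 100, s / 100)
        expected = 0 if n < w else (n - w) // s + 1
        assert len(segs) == expected
        # no segment crosses the end; offsets form an arithmetic progression
        assert all(seg.offset + len(seg) <= n for seg in segs)
        assert [seg.offset for seg in segs] == [i * s for i in range(len(segs))]


class TestSplit:
    def test_published_corpus_counts(self):
        plan = make_split(29948, seed=0)
        assert len(plan.train_ids) == 26953
        assert len(plan.test_ids) == 2995

    def test_published_noise_counts(self):
        plan = make_split(426, seed=0)
        assert len(plan.train_ids) == 383
        assert len(plan.test_ids) == 43

    def test_split_is_deterministic_and_partitions(self):
        a = make_split(10, seed=5)
        b = make_split(10, seed=5)
        assert a == b
        assert sorted(a.train_ids + a.test_ids) == list(range(10))
        assert set(a.val_ids) <= set(a.train_ids)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 5000))
    def test_floor_arithmetic_for_all_sizes(self, n):
        plan = make_split(n, seed=1)
        n_train = int(np.floor(0.9 * n))
        assert len(plan.train_ids) == n_train
        assert len(plan.test_ids) == n - n_train
        assert len(plan.val_ids) == int(np.floor(0.05 * n_train))


class TestMixing:
    def test_equal_energy_zero_db_gain_is_one(self):
        c = Segment(np.array([1.0, -1.0]))
        d = Segment(np.array([-1.0, 1.0]))
        assert mixing_gain(c, d, 0.0) == pytest.approx(1.0)

    def test_equal_energy_minus_ten_db_gain_is_sqrt_ten(self):
        c = Segment(np.array([1.0, 1.0]))
        d = Segment(np.array([1.0, 1.0]))
        assert mixing_gain(c, d, -10.0) == pytest.approx(np.sqrt(10.0))

    def test_unequal_energy_closed_form(self):
        c = Segment(np.array([2.0, 0.0]))  # energy 4
        d = Segment(np.array([1.0, 0.0]))  # energy 1
        assert mixing_gain(c, d, 0.0) == pytest.approx(2.0)

    def test_zero_energy_errors_are_distinct(self):
        z = Segment(np.zeros(4))
        o = Segment(np.ones(4))
        with pytest.raises(ZeroEnergyError) as e1:
            mixing_gain(z, o, 0.0)
        with pytest.raises(ZeroEnergyError) as e2:
            mixing_gain(o, z, 0.0)
        assert e1.value.which == "clean" and e2.value.which == "noise"

    def test_orthogonal_unit_vectors_at_zero_db(self):
        rec = mix_at_snr(Segment(np.array([1.0, 0.0])), Segment(np.array([0.0, 1.0])), 0.0)
        np.testing.assert_allclose(rec.mixture.samples, [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mix_at_snr(Segment(np.ones(4)), Segment(np.ones(5)), 0.0)

    def test_clean_is_never_rescaled(self):
        c = Segment(np.array([0.3, -0.2, 0.5]))
        rec = mix_at_snr(c, Segment(np.array([0.1, 0.1, -0.1])), -5.0)
        np.testing.assert_array_equal(rec.clean.samples, c.samples)
        np.testing.assert_allclose(
            rec.mixture.samples, c.samples + rec.gain * rec.noise.samples
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        snr=st.floats(-20, 20, allow_nan=False),
    )
    def test_mixture_attains_target_snr_exactly(self, seed, snr):
        rng = np.random.default_rng(seed)
        c = Segment(rng.normal(size=64))
        d = Segment(rng.normal(size=64))
        rec = mix_at_snr(c, d, snr)
        assert snr_db(c.samples, rec.mixture.samples) == pytest.approx(snr, abs=1e-6)


class TestNoisySet:
    def test_environment_counts_for_published_sizes(self):
        clean = [Segment(np.ones(4), f"c{i}") for i in range(3)]
        noise_train = [Segment(np.full(4, 0.5), f"n{i}") for i in range(383)]
        _, n_env = build_noisy_set(clean, noise_train, DEFAULT_SNRS_DB, 0)
        assert n_env == 1915
        noise_test = noise_train + [Segment(np.full(4, 0.5), f"m{i}") for i in range(43)]
        _, n_env_test = build_noisy_set(clean, noise_test, DEFAULT_SNRS_DB, 0)
        assert n_env_test == 2130

    def test_single_pair_single_snr(self):
        records, n_env = build_noisy_set(
            [Segment(np.ones(4), "c")], [Segment(np.ones(4), "n")], (-5.0,), 3
        )
        assert n_env == 1 and len(records) == 1
        assert records[0].snr_db == -5.0
        assert records[0].noise.source_id == "n"

    def test_pairing_is_seeded(self):
        clean = [Segment(np.ones(8), f"c{i}") for i in range(20)]
        noise = [Segment(np.full(8, 0.3), f"n{i}") for i in range(7)]
        a, _ = build_noisy_set(clean, noise, DEFAULT_SNRS_DB, 99)
        b, _ = build_noisy_set(clean, noise, DEFAULT_SNRS_DB, 99)
        assert [(r.noise.source_id, r.snr_db) for r in a] == [
            (r.noise.source_id, r.snr_db) for r in b
        ]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_noisy_set([], [Segment(np.ones(4))], DEFAULT_SNRS_DB, 0)
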