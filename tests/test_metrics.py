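"""SNR / SegSNR / LLR against brute-force oracles.

The oracles here deliberately avoid the implementation's code paths:
direct sums for the energy ratios, and a dense Toeplitz normal-equation
solve (``scipy.linalg``) for LPC.
"""

import numpy as np
import pytest
from scipy.linalg import solve, toeplitz

from tcenv.metrics import (
    FramePlan,
    SEGSNR_PERFECT_DB,
    levinson_durbin,
    llr,
    lpc,
    seg_snr_db,
    snr_db,
)


def lpc_oracle(frame: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense solve of the autocorrelation normal equations R a = -r."""
    x = frame * np.hamming(frame.size)
    n = x.size
    full = np.correlate(x, x, mode="full")
    r = full[n - 1 : n + order] / n
    a_tail = solve(toeplitz(r[:-1]), -r[1:], assume_a="pos")
    return np.concatenate([[1.0], a_tail]), r


class TestSNR:
    def test_zero_estimate_gives_zero_db(self):
        y = np.array([1.0, -2.0, 3.0])
        assert snr_db(y, np.zeros(3)) == pytest.approx(0.0)

    def test_hand_computed_ratio(self):
        assert snr_db([1, 1, 1, 1], [1, 1, 1, 0]) == pytest.approx(
            10 * np.log10(4), abs=1e-9
        )

    def test_perfect_reconstruction_is_infinite(self):
        y = np.array([0.5, -0.5])
        assert snr_db(y, y) == np.inf

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(0)
        y, yh = rng.normal(size=50), rng.normal(size=50)
        for c in (1e-3, 0.5, 7.0):
            assert snr_db(c * y, c * yh) == pytest.approx(snr_db(y, yh))

    def test_zero_energy_and_mismatch_rejected(self):
        with pytest.raises(ValueError):
            snr_db(np.zeros(4), np.ones(4))
        with pytest.raises(ValueError):
            snr_db(np.ones(4), np.ones(5))


class TestSegSNR:
    def test_hand_computed_two_frames(self):
        y = np.array([1.0, 0.0, 2.0, 0.0])
        yh = np.array([0.0, 0.0, 2.0, 2.0])
        mean, frames = seg_snr_db(y, yh, FramePlan(2, 2))
        np.testing.assert_allclose(frames, [0.0, 0.0], atol=1e-12)
        assert mean == pytest.approx(0.0)

    def test_zero_estimate_gives_zero_db_per_frame(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=4096) + 0.1  # no silent frame
        mean, _ = seg_snr_db(y, np.zeros_like(y), FramePlan(1024, 1024))
        assert mean == pytest.approx(0.0)

    def test_single_frame_reduces_to_snr(self):
        rng = np.random.default_rng(2)
        y, yh = rng.normal(size=1024), rng.normal(size=1024)
        mean, _ = seg_snr_db(y, yh, FramePlan(1024, 1024))
        assert mean == pytest.approx(snr_db(y, yh))

    def test_silent_frames_excluded_and_perfect_frames_capped(self):
        y = np.concatenate([np.zeros(4), np.ones(4)])
        yh = y.copy()
        mean, frames = seg_snr_db(y, yh, FramePlan(4, 4))
        assert frames.size == 1 and mean == SEGSNR_PERFECT_DB

    def test_optional_clamp(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=2048)
        mean, frames = seg_snr_db(y, y * 0.999999, FramePlan(1024, 1024), clamp_db=(-10, 35))
        assert np.all(frames <= 35.0) and mean <= 35.0


class TestLPC:
    def test_matches_dense_normal_equation_solve(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            frame = rng.normal(size=256)
            model = lpc(frame, order=12)
            a_ref, r_ref = lpc_oracle(frame, 12)
            np.testing.assert_allclose(model.coeffs, a_ref, atol=1e-8)
            np.testing.assert_allclose(model.autocorr, r_ref, atol=1e-12)

    def test_ar1_recovers_coefficient(self):
        rng = np.random.default_rng(5)
        x = np.zeros(20000)
        eps = rng.normal(size=20000)
        for i in range(1, 20000):
            x[i] = 0.5 * x[i - 1] + eps[i]
        model = lpc(x[1000:], order=1, window=False)
        assert model.coeffs[1] == pytest.approx(-0.5, abs=0.05)

    def test_white_noise_is_nearly_unpredictable(self):
        rng = np.random.default_rng(6)
        model = lpc(rng.normal(size=1024), order=1)
        assert abs(model.coeffs[1]) < 0.2

    def test_levinson_equals_dense_solve_high_order(self):
        rng = np.random.default_rng(7)
        frame = rng.normal(size=512)
        x = frame * np.hamming(512)
        full = np.correlate(x, x, "full")
        r = full[511 : 511 + 17] / 512
        a = levinson_durbin(r)
        a_ref = np.concatenate([[1.0], solve(toeplitz(r[:-1]), -r[1:], assume_a="pos")])
        np.testing.assert_allclose(a, a_ref, atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lpc(np.zeros(64), 4)
        with pytest.raises(ValueError):
            lpc(np.ones(4), 8)


class TestLLR:
    def test_identical_signals_give_zero(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=2048)
        mean, frames, skipped = llr(y, y, FramePlan(1024, 1024))
        assert mean == 0.0 and np.all(frames == 0.0) and skipped == 0

    def test_per_frame_llr_is_nonnegative(self):
        """The clean coefficients minimise a^T R a, so the ratio >= 1."""
        rng = np.random.default_rng(9)
        y = rng.normal(size=8192)
        yh = y + 0.3 * rng.normal(size=8192)
        _, frames, _ = llr(y, yh, FramePlan(1024, 1024))
        assert np.all(frames >= -1e-9)

    def test_matches_brute_force_quadratic_forms(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=3072)
        yh = y + 0.5 * rng.normal(size=3072)
        plan = FramePlan(1024, 1024)
        mean, frames, _ = llr(y, yh, plan, order=16)
        for k, (yf, hf) in enumerate(zip(plan.frames(y), plan.frames(yh))):
            a_clean, r = lpc_oracle(yf, 16)
            a_enh, _ = lpc_oracle(hf, 16)
            R = toeplitz(r)
            expected = np.log10((a_enh @ R @ a_enh) / (a_clean @ R @ a_clean))
            assert frames[k] == pytest.approx(expected, abs=1e-8)
        assert mean == pytest.approx(frames.mean())

    def test_degenerate_frames_are_skipped_and_counted(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([rng.normal(size=1024), np.zeros(1024)])
        yh = y + 0.1
        _, frames, skipped = llr(y, yh, FramePlan(1024, 1024))
        assert skipped == 1 and frames.size == 1
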