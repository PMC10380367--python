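"""Objective enhancement metrics: SNR, segmental SNR, and log-likelihood
ratio (LLR) with autocorrelation-method LPC.

All three compare a clean reference ``y`` with an enhanced estimate
``y_hat``:

* ``SNR = 10 log10( sum y^2 / sum (y - y_hat)^2 )`` over the whole signal;
* ``SegSNR`` is the same ratio computed per fixed-length frame and
  averaged over frames;
* ``LLR`` compares the all-pole (LPC) spectral envelopes:
  ``log10( a_hat^T R a_hat / a^T R a )`` per frame, where ``a`` / ``a_hat``
  are the LPC coefficient vectors of the clean / enhanced frame and ``R``
  is the autocorrelation matrix of the clean frame.  Since ``a`` minimises
  the quadratic form, each per-frame value is non-negative (up to
  round-off); 0 means identical envelopes.

LPC coefficients are found with the Levinson–Durbin recursion on the
biased autocorrelation of a Hamming-windowed frame (order 16 by default).
The frame length defaults to 1024 samples (32 ms at 32 kHz),
non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FramePlan",
    "LPCModel",
    "MetricsReport",
    "snr_db",
    "seg_snr_db",
    "lpc",
    "llr",
    "evaluate",
    "SEGSNR_PERFECT_DB",
]

#: SegSNR contribution of a frame reconstructed exactly (instead of +inf).
SEGSNR_PERFECT_DB = 99.0


@dataclass(frozen=True)
class FramePlan:
    """Fixed-length framing: ``frame_len`` samples every ``hop`` samples."""

    frame_len: int = 1024
    hop: int = 1024

    def __post_init__(self):
        if self.frame_len < 2 or self.hop < 1:
            raise ValueError("frame_len >= 2 and hop >= 1 required")

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.frame_len:
            return 0
        return (n_samples - self.frame_len) // self.hop + 1

    def frames(self, x: np.ndarray) -> np.ndarray:
        f = self.n_frames(x.size)
        idx = np.arange(self.frame_len) + self.hop * np.arange(f)[:, None]
        return x[idx]


@dataclass(frozen=True)
class LPCModel:
    """All-pole model: A(z) = 1 + sum_{k=1..p} a_k z^-k."""

    order: int
    coeffs: np.ndarray  # length order+1, coeffs[0] == 1
    autocorr: np.ndarray  # lags r[0..order]

    def toeplitz(self) -> np.ndarray:
        from scipy.linalg import toeplitz

        return toeplitz(self.autocorr)


@dataclass(frozen=True)
class MetricsReport:
    snr_db: float
    seg_snr_db: float
    llr: float
    seg_snr_frames: np.ndarray = field(default_factory=lambda: np.array([]))
    llr_frames: np.ndarray = field(default_factory=lambda: np.array([]))
    llr_skipped: int = 0


def _check_pair(y: np.ndarray, y_hat: np.ndarray):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def snr_db(y, y_hat) -> float:
    """Whole-signal SNR in dB; +inf when the residual is exactly zero."""
    y, y_hat = _check_pair(y, y_hat)
    e_sig = float(np.sum(y**2))
    if e_sig <= 0:
        raise ValueError("clean signal has zero energy")
    e_res = float(np.sum((y - y_hat) ** 2))
    if e_res == 0.0:
        return float("inf")
    return 10.0 * np.log10(e_sig / e_res)


def seg_snr_db(
    y,
    y_hat,
    plan: FramePlan | None = None,
    clamp_db: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean per-frame SNR in dB, plus the per-frame vector.

    Frames with zero clean energy are excluded; a frame with zero residual
    contributes :data:`SEGSNR_PERFECT_DB`.  ``clamp_db`` optionally clamps
    per-frame values (e.g. ``(-10, 35)`` as in the speech literature);
    off by default.
    """
    y, y_hat = _check_pair(y, y_hat)
    plan = plan or FramePlan()
    if plan.n_frames(y.size) == 0:
        raise ValueError("signal shorter than one frame")
    yf = plan.frames(y)
    rf = plan.frames(y - y_hat)
    e_sig = np.sum(yf**2, axis=1)
    e_res = np.sum(rf**2, axis=1)
    valid = e_sig > 0
    with np.errstate(divide="ignore"):
        vals = 10.0 * np.log10(
            np.divide(e_sig, e_res, out=np.full_like(e_sig, np.inf), where=e_res > 0)
        )
    vals = np.where(np.isinf(vals), SEGSNR_PERFECT_DB, vals)
    per_frame = vals[valid]
    if clamp_db is not None:
        per_frame = np.clip(per_frame, *clamp_db)
    if per_frame.size == 0:
        raise ValueError("no frame with nonzero clean energy")
    return float(np.mean(per_frame)), per_frame


def _biased_autocorr(frame: np.ndarray, order: int) -> np.ndarray:
    n = frame.size
    full = np.correlate(frame, frame, mode="full")
    return full[n - 1 : n + order] / n


def levinson_durbin(r: np.ndarray) -> np.ndarray:
    """Solve the Toeplitz normal equations; returns [1, a_1, ..., a_p]."""
    p = r.size - 1
    a = np.zeros(p + 1)
    a[0] = 1.0
    err = r[0]
    if err <= 0:
        raise ValueError("autocorrelation at lag 0 must be positive")
    for m in range(1, p + 1):
        acc = r[m] + np.dot(a[1:m], r[m - 1 : 0 : -1])
        k = -acc / err
        # reflection update: a_new[i] = a[i] + k * a[m - i]
        prev = a[: m + 1].copy()
        for i in range(1, m):
            a[i] = prev[i] + k * prev[m - i]
        a[m] = k
        err *= 1.0 - k * k
        if err <= 0:
            err = np.finfo(float).tiny
    return a


def lpc(frame: np.ndarray, order: int = 16, window: bool = True) -> LPCModel:
    """Autocorrelation-method LPC of a frame via Levinson–Durbin.

    The frame is Hamming-windowed (unless ``window=False``) and the biased
    autocorrelation estimate is used, which guarantees a stable minimum-
    phase solution.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise ValueError("frame must be 1-D")
    if order < 1 or order >= frame.size:
        raise ValueError("need 1 <= order < frame length")
    if not np.any(frame):
        raise ValueError("all-zero frame has no LPC model")
    x = frame * np.hamming(frame.size) if window else frame
    r = _biased_autocorr(x, order)
    if r[0] <= 0:
        raise ValueError("degenerate frame (zero windowed energy)")
    a = levinson_durbin(r)
    return LPCModel(order=order, coeffs=a, autocorr=r)


def _quad_form(a: np.ndarray, r: np.ndarray) -> float:
    """a^T R a for symmetric Toeplitz R given by lags r[0..p] — O(p^2)."""
    p = a.size - 1
    total = r[0] * float(np.dot(a, a))
    for lag in range(1, p + 1):
        total += 2.0 * r[lag] * float(np.dot(a[:-lag], a[lag:]))
    return total


def llr(
    y,
    y_hat,
    plan: FramePlan | None = None,
    order: int = 16,
    log_base: float = 10.0,
) -> tuple[float, np.ndarray, int]:
    """Mean per-frame log-likelihood ratio, per-frame vector, skip count.

    Frames where either signal is degenerate (all zero) are skipped and
    counted.  ``log_base`` selects the logarithm (10 by default).
    """
    y, y_hat = _check_pair(y, y_hat)
    plan = plan or FramePlan()
    if plan.n_frames(y.size) == 0:
        raise ValueError("signal shorter than one frame")
    vals = []
    skipped = 0
    for yf, hf in zip(plan.frames(y), plan.frames(y_hat)):
        try:
            clean_model = lpc(yf, order)
            enh_model = lpc(hf, order)
        except ValueError:
            skipped += 1
            continue
        r = clean_model.autocorr
        num = _quad_form(enh_model.coeffs, r)
        den = _quad_form(clean_model.coeffs, r)
        vals.append(np.log(num / den) / np.log(log_base))
    if not vals:
        raise ValueError("no valid frame for LLR")
    per_frame = np.asarray(vals)
    return float(np.mean(per_frame)), per_frame, skipped


def evaluate(
    y,
    y_hat,
    plan: FramePlan | None = None,
    lpc_order: int = 16,
) -> MetricsReport:
    """All three metrics for one (clean, enhanced) pair."""
    plan = plan or FramePlan()
    seg, seg_frames = seg_snr_db(y, y_hat, plan)
    llr_mean, llr_frames, skipped = llr(y, y_hat, plan, lpc_order)
    return MetricsReport(
        snr_db=snr_db(y, y_hat),
        seg_snr_db=seg,
        llr=llr_mean,
        seg_snr_frames=seg_frames,
        llr_frames=llr_frames,
        llr_skipped=skipped,
    )
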