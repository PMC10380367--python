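"""Training objectives over (clean, estimate) pairs.

Three candidates: mean squared error, mean absolute error (L1), and the
negative SNR

    -10 log10( sum y^2 / (sum (y - y_hat)^2 + eps) )

which directly maximises the evaluation SNR.  All accept either autograd
:class:`~tcenv.nn.Tensor` inputs (differentiable, for training) or plain
numpy arrays, with shape ``(batch, ...)`` or unbatched; the batch
reduction is the mean over items.
"""

from __future__ import annotations

import numpy as np

from .nn.tensor import Tensor

__all__ = ["mse_loss", "l1_loss", "negative_snr_loss", "get_loss", "LOSSES"]


def _check(y, y_hat):
    ys = y.shape if isinstance(y, Tensor) else np.shape(y)
    hs = y_hat.shape if isinstance(y_hat, Tensor) else np.shape(y_hat)
    if ys != hs:
        raise ValueError(f"shape mismatch: {ys} vs {hs}")
    if int(np.prod(ys)) < 1:
        raise ValueError("empty input")


def mse_loss(y, y_hat):
    """Mean squared sample difference."""
    _check(y, y_hat)
    d = y - y_hat
    return (d * d).mean() if isinstance(d, Tensor) else float(np.mean(d * d))


def l1_loss(y, y_hat):
    """Mean absolute sample difference."""
    _check(y, y_hat)
    d = y - y_hat
    return d.abs().mean() if isinstance(d, Tensor) else float(np.mean(np.abs(d)))


def negative_snr_loss(y, y_hat, eps: float = 1e-8):
    """Negative SNR in dB; equals ``-snr_db(y, y_hat)`` up to *eps*.

    *eps* guards the residual-energy denominator during training; pass
    ``eps=0`` for exact agreement with the metric on nonzero residuals.
    Per-item SNRs are averaged when the input is batched (2-D).
    """
    _check(y, y_hat)
    tensor_mode = isinstance(y, Tensor) or isinstance(y_hat, Tensor)
    if tensor_mode:
        y = y if isinstance(y, Tensor) else Tensor(y)
        y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(y_hat)
        axis = tuple(range(1, y.ndim)) if y.ndim > 1 else None
        e_sig = (y * y).sum(axis=axis)
        if np.any(e_sig.data <= 0):
            raise ValueError("clean signal has zero energy")
        d = y - y_hat
        e_res = (d * d).sum(axis=axis) + eps
        return (-10.0 * (e_sig / e_res).log10()).mean()
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    axis = tuple(range(1, y.ndim)) if y.ndim > 1 else None
    e_sig = np.sum(y * y, axis=axis)
    if np.any(e_sig <= 0):
        raise ValueError("clean signal has zero energy")
    e_res = np.sum((y - y_hat) ** 2, axis=axis) + eps
    return float(np.mean(-10.0 * np.log10(e_sig / e_res)))


LOSSES = {"mse": mse_loss, "l1": l1_loss, "negative_snr": negative_snr_loss}


def get_loss(name: str):
    """Look up a loss by its config key."""
    try:
        return LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(LOSSES)}") from None
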