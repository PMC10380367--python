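"""Strided / dilated / grouped 1-D convolution and its transpose.

Forward passes are built on ``sliding_window_view`` + ``einsum``; backward
passes are written explicitly (gradient w.r.t. the input of a convolution
is a transposed convolution and vice versa).  Array layouts follow the
usual DL convention: activations ``(batch, channels, time)``, convolution
weights ``(out_ch, in_ch/groups, kernel)``, transposed-convolution weights
``(in_ch, out_ch/groups, kernel)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = ["conv1d", "conv_transpose1d"]


def _im2col(x: np.ndarray, kernel: int, stride: int, dilation: int) -> np.ndarray:
    """(B, C, T_padded) -> windows (B, C, T_out, K)."""
    span = (kernel - 1) * dilation + 1
    win = sliding_window_view(x, span, axis=2)  # (B, C, T_padded-span+1, span)
    return win[:, :, ::stride, ::dilation]


def _conv1d_forward(x, w, stride, padding, dilation, groups):
    b, cin, _ = x.shape
    cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    cols = _im2col(xp, w.shape[2], stride, dilation)  # (B, Cin, L, K)
    if groups == 1:
        y = np.einsum("bclk,ock->bol", cols, w, optimize=True)
    else:
        cols_g = cols.reshape(b, groups, cin // groups, cols.shape[2], -1)
        w_g = w.reshape(groups, cout // groups, cin // groups, -1)
        y = np.einsum("bgclk,gock->bgol", cols_g, w_g, optimize=True)
        y = y.reshape(b, cout, -1)
    return np.ascontiguousarray(y), cols


def _conv1d_grad_w(cols, grad, cin, groups):
    b = grad.shape[0]
    cout = grad.shape[1]
    if groups == 1:
        return np.einsum("bclk,bol->ock", cols, grad, optimize=True)
    cols_g = cols.reshape(b, groups, cin // groups, cols.shape[2], -1)
    grad_g = grad.reshape(b, groups, cout // groups, -1)
    gw = np.einsum("bgclk,bgol->gock", cols_g, grad_g, optimize=True)
    return gw.reshape(cout, cin // groups, -1)


def _conv1d_grad_x(grad, w, x_shape, stride, padding, dilation, groups):
    b, cin, t = x_shape
    kernel = w.shape[2]
    l_out = grad.shape[2]
    gxp = np.zeros((b, cin, t + 2 * padding), dtype=grad.dtype)
    if groups == 1:
        # contribution per kernel tap: gxp[:, :, k*d + s*l] += grad · w[:, :, k]
        contrib = np.einsum("bol,ock->bclk", grad, w, optimize=True)
    else:
        w_g = w.reshape(groups, w.shape[0] // groups, cin // groups, kernel)
        grad_g = grad.reshape(b, groups, -1, l_out)
        contrib = np.einsum("bgol,gock->bgclk", grad_g, w_g, optimize=True)
        contrib = contrib.reshape(b, cin, l_out, kernel)
    for k in range(kernel):
        start = k * dilation
        gxp[:, :, start : start + stride * l_out : stride] += contrib[:, :, :, k]
    return gxp[:, :, padding : padding + t]


def conv1d(
    x,
    weight,
    bias=None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Cross-correlation along the last axis, as in torch's ``conv1d``."""
    x, weight = as_tensor(x), as_tensor(weight)
    y, cols = _conv1d_forward(x.data, weight.data, stride, padding, dilation, groups)

    def backward(g):
        g = np.ascontiguousarray(g)
        gx = _conv1d_grad_x(
            g, weight.data, x.data.shape, stride, padding, dilation, groups
        )
        gw = _conv1d_grad_w(cols, g, x.data.shape[1], groups)
        return gx, gw

    out = Tensor._make(y, (x, weight), backward)
    if bias is not None:
        out = out + as_tensor(bias).reshape(1, -1, 1)
    return out


def _convt_forward(x, w, stride, padding, groups, output_padding):
    b, cin, t = x.shape
    kernel = w.shape[2]
    cout = w.shape[1] * groups
    t_out = (t - 1) * stride + kernel - 2 * padding + output_padding
    if padding < output_padding:
        raise ValueError("output_padding must not exceed padding")
    buf = np.zeros((b, cout, (t - 1) * stride + kernel), dtype=x.dtype)
    if groups == 1:
        contrib = np.einsum("bct,cok->botk", x, w, optimize=True)
    else:
        x_g = x.reshape(b, groups, cin // groups, t)
        w_g = w.reshape(groups, cin // groups, -1, kernel)
        contrib = np.einsum("bgct,gcok->bgotk", x_g, w_g, optimize=True)
        contrib = contrib.reshape(b, cout, t, kernel)
    for k in range(kernel):
        buf[:, :, k : k + stride * t : stride] += contrib[:, :, :, k]
    return buf[:, :, padding : padding + t_out]


def conv_transpose1d(
    x,
    weight,
    bias=None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
    output_padding: int = 0,
) -> Tensor:
    """Transposed (fractionally strided) convolution, torch layout."""
    x, weight = as_tensor(x), as_tensor(weight)
    y = _convt_forward(x.data, weight.data, stride, padding, groups, output_padding)
    b, cin, t = x.data.shape
    kernel = weight.data.shape[2]

    def backward(g):
        # pad grad back to the un-cropped buffer, then gather per tap
        right = (t - 1) * stride + kernel - padding - g.shape[2]
        gbuf = np.pad(g, ((0, 0), (0, 0), (padding, right)))
        taps = _im2col(gbuf, kernel, stride, 1)  # (B, Cout, T, K)
        if groups == 1:
            gx = np.einsum("botk,cok->bct", taps, weight.data, optimize=True)
            gw = np.einsum("bct,botk->cok", x.data, taps, optimize=True)
        else:
            taps_g = taps.reshape(b, groups, -1, t, kernel)
            x_g = x.data.reshape(b, groups, cin // groups, t)
            w_g = weight.data.reshape(groups, cin // groups, -1, kernel)
            gx = np.einsum("bgotk,gcok->bgct", taps_g, w_g, optimize=True)
            gx = gx.reshape(b, cin, t)
            gw = np.einsum("bgct,bgotk->gcok", x_g, taps_g, optimize=True)
            gw = gw.reshape(cin, -1, kernel)
        return np.ascontiguousarray(gx), gw

    out = Tensor._make(y, (x, weight), backward)
    if bias is not None:
        out = out + as_tensor(bias).reshape(1, -1, 1)
    return out
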