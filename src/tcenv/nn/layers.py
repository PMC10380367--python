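"""Neural-network layers on top of the autograd tensor.

Initialisation follows the common Kaiming-uniform convention
(``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` for weights and biases), with the
random stream supplied explicitly so that model construction is fully
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .conv import conv1d, conv_transpose1d
from .tensor import Tensor

__all__ = [
    "Module",
    "Conv1d",
    "ConvTranspose1d",
    "Linear",
    "BatchNorm1d",
    "LayerNorm",
    "MultiheadSelfAttention",
]

_DTYPE = np.float32


class Module:
    """Base class: parameter registration, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for name, m in self._modules.items():
            out.extend(m.named_buffers(prefix + name + "."))
        return out

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name.startswith("buffer:"):
                self._set_buffer(name[len("buffer:") :], arr)
            else:
                p = params[name]
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                p.data = arr.astype(p.data.dtype)

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        mod = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod._buffers[leaf] = arr.copy()
        object.__setattr__(mod, leaf, mod._buffers[leaf])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, shape).astype(_DTYPE), requires_grad=True)


class Conv1d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels not divisible by groups")
        fan_in = (in_ch // groups) * kernel
        self.weight = _param(rng, (out_ch, in_ch // groups, kernel), fan_in)
        self.bias = _param(rng, (out_ch,), fan_in)
        self.stride, self.padding = stride, padding
        self.dilation, self.groups = dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding,
            dilation=self.dilation, groups=self.groups,
        )


class ConvTranspose1d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        output_padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel
        self.weight = _param(rng, (in_ch, out_ch, kernel), fan_in)
        self.bias = _param(rng, (out_ch,), fan_in)
        self.stride, self.padding = stride, padding
        self.output_padding = output_padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding,
            output_padding=self.output_padding,
        )


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = _param(rng, (in_f, out_f), in_f)
        self.bias = _param(rng, (out_f,), in_f)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Normalises (batch, C, T) per channel over batch and time.

    Running statistics are tracked with momentum 0.1 and used in eval mode;
    they are buffers, not trainable parameters.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=_DTYPE), requires_grad=True)
        self.eps, self.momentum = eps, momentum
        self._buffers["running_mean"] = np.zeros(channels, dtype=_DTYPE)
        self._buffers["running_var"] = np.ones(channels, dtype=_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.ravel().astype(_DTYPE)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.ravel().astype(_DTYPE)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    """Normalises over the trailing feature axis of (batch, L, d)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=_DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention over (batch, L, d)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        return x.reshape(b, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        q = self._split(self.q_proj(x)) * (self.d_head**-0.5)
        k = self._split(self.k_proj(x))
        v = self._split(self.v_proj(x))
        scores = q @ k.transpose(0, 1, 3, 2)  # (B, h, L, L)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.out_proj(ctx)
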