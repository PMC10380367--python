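"""T-CENV: time-domain Conformer-augmented enhancement network.

The architecture is a 1-D convolutional encoder-decoder (U-Net style)
operating directly on the raw waveform, with a stack of Conformer blocks
modelling the latent sequence between encoder and decoder:

* encoder — eight dilated-convolution downsampling layers (kernel 15,
  stride 2), each followed by batch normalization and LeakyReLU(0.1);
  output channels 16, 32, 64, 64, 128, 128, 256, 256;
* bottleneck — a 256→256 kernel-15 convolution (batch-norm + LeakyReLU)
  between encoder and Conformer stack;
* Conformer blocks — macaron structure FFN → self-attention → convolution
  module → FFN with pre-norm residuals (half-step on the two FFNs) and a
  final layer norm; the convolution module is pointwise (expansion 2) →
  GLU → depthwise → batch-norm → swish → pointwise;
* decoder — eight transposed-convolution upsampling layers (kernel 5,
  stride 2) mirroring the encoder; the input of each is the channel
  concatenation of the previous decoder output and the matching encoder
  output (hence twice the encoder layer's channel count); the final layer
  projects to one channel with no normalization or activation so the
  output is an unconstrained waveform.

Overall stride is 2^depth, so the forward pass requires the input length
to be a multiple of it; :func:`enhance` pads and crops to lift that
restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io_wav import Waveform
from .nn.tensor import Tensor

__all__ = [
    "TCENVConfig",
    "ParameterCount",
    "ConformerBlock",
    "Encoder",
    "TCENV",
    "build_encoder",
    "build_conformer_block",
    "build_tcenv",
    "count_parameters",
    "enhance",
    "REFERENCE_CONFIG",
    "tiny_config",
]


@dataclass(frozen=True)
class TCENVConfig:
    """Complete architecture hyperparameters.

    The feed-forward hidden width ``ffn_hidden`` (1286) was calibrated so
    that the per-block parameter count, together with the published layer
    plan, reproduces the published model sizes; see docs/methods.md and
    scripts/calibrate_conformer.py.
    """

    encoder_channels: tuple[int, ...] = (16, 32, 64, 64, 128, 128, 256, 256)
    conv_kernel: int = 15
    conv_stride: int = 2
    dilations: tuple[int, ...] = (1, 2, 4, 8, 1, 2, 4, 8)
    leaky_slope: float = 0.1
    deconv_kernel: int = 5
    deconv_stride: int = 2
    deconv_padding: int = 2
    n_conformer_layers: int = 2
    n_heads: int = 4
    ffn_hidden: int = 1286
    pointwise_expansion: int = 2
    depthwise_kernel: int = 31
    residual_half_step: bool = True
    bottleneck_enabled: bool = True
    bottleneck_kernel: int = 15
    seed: int = 0

    def __post_init__(self):
        if len(self.dilations) != len(self.encoder_channels):
            raise ValueError("need one dilation per encoder layer")
        if self.d_model % self.n_heads:
            raise ValueError("last encoder channel count must divide by n_heads")
        if self.n_conformer_layers < 0:
            raise ValueError("n_conformer_layers must be >= 0")
        if self.conv_kernel % 2 == 0 or self.deconv_kernel % 2 == 0:
            raise ValueError("odd kernels required for symmetric padding")

    @property
    def d_model(self) -> int:
        return self.encoder_channels[-1]

    @property
    def depth(self) -> int:
        return len(self.encoder_channels)

    @property
    def total_stride(self) -> int:
        return self.conv_stride**self.depth


#: Configuration reproducing the published layer plan and model sizes.
REFERENCE_CONFIG = TCENVConfig()


def tiny_config(seed: int = 0) -> TCENVConfig:
    """Desk-scale variant for CPU demonstrations and tests: four encoder
    layers at a quarter of the reference widths, one Conformer block."""
    return TCENVConfig(
        encoder_channels=(4, 8, 16, 16),
        dilations=(1, 2, 4, 8),
        n_conformer_layers=1,
        n_heads=2,
        ffn_hidden=32,
        depthwise_kernel=15,
        seed=seed,
    )


@dataclass(frozen=True)
class ParameterCount:
    total: int
    per_block: dict = field(default_factory=dict)

    @property
    def millions(self) -> float:
        return round(self.total / 1e6, 2)

    def __post_init__(self):
        if self.per_block and sum(self.per_block.values()) != self.total:
            raise ValueError("per-block counts do not sum to total")


class _ConvBNAct(nn.Module):
    """conv -> batch-norm -> LeakyReLU, the encoder/bottleneck unit."""

    def __init__(self, in_ch, out_ch, kernel, stride, dilation, slope, rng):
        super().__init__()
        self.conv = nn.Conv1d(
            in_ch, out_ch, kernel, stride=stride,
            padding=dilation * (kernel - 1) // 2, dilation=dilation, rng=rng,
        )
        self.bn = nn.BatchNorm1d(out_ch)
        self.slope = slope

    def forward(self, x):
        return self.bn(self.conv(x)).leaky_relu(self.slope)


class Encoder(nn.Module):
    """Stack of dilated-conv downsampling layers; retains per-layer
    outputs for the decoder's skip connections."""

    def __init__(self, cfg: TCENVConfig, rng: np.random.Generator):
        super().__init__()
        in_ch = 1
        for i, (out_ch, dil) in enumerate(zip(cfg.encoder_channels, cfg.dilations)):
            setattr(
                self,
                f"layer{i}",
                _ConvBNAct(
                    in_ch, out_ch, cfg.conv_kernel, cfg.conv_stride, dil,
                    cfg.leaky_slope, rng,
                ),
            )
            in_ch = out_ch
        self.depth = cfg.depth
        self.total_stride = cfg.total_stride

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        if x.shape[-1] % self.total_stride:
            raise ValueError(
                f"input length {x.shape[-1]} not divisible by {self.total_stride}"
            )
        skips = []
        for i in range(self.depth):
            x = getattr(self, f"layer{i}")(x)
            skips.append(x)
        return x, skips


class _FFN(nn.Module):
    def __init__(self, d, hidden, rng):
        super().__init__()
        self.norm = nn.LayerNorm(d)
        self.lin1 = nn.Linear(d, hidden, rng)
        self.lin2 = nn.Linear(hidden, d, rng)

    def forward(self, x):
        return self.lin2(self.lin1(self.norm(x)).swish())


class _ConvModule(nn.Module):
    """pointwise(expand) -> GLU -> depthwise -> BN -> swish -> pointwise."""

    def __init__(self, d, expansion, depthwise_kernel, rng):
        super().__init__()
        self.norm = nn.LayerNorm(d)
        self.pw1 = nn.Conv1d(d, expansion * d, 1, rng=rng)
        self.dw = nn.Conv1d(
            d, d, depthwise_kernel,
            padding=(depthwise_kernel - 1) // 2, groups=d, rng=rng,
        )
        self.bn = nn.BatchNorm1d(d)
        self.pw2 = nn.Conv1d(d, d, 1, rng=rng)
        self.d = d

    def forward(self, x):
        h = self.norm(x).transpose(0, 2, 1)  # (B, d, L)
        h = self.pw1(h)
        a, b = h[:, : self.d, :], h[:, self.d :, :]
        h = a * b.sigmoid()  # GLU
        h = self.bn(self.dw(h)).swish()
        return self.pw2(h).transpose(0, 2, 1)


class ConformerBlock(nn.Module):
    """Macaron Conformer block over (batch, L, d_model), shape-preserving."""

    def __init__(self, cfg: TCENVConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.d_model
        self.ffn1 = _FFN(d, cfg.ffn_hidden, rng)
        self.attn_norm = nn.LayerNorm(d)
        self.attn = nn.MultiheadSelfAttention(d, cfg.n_heads, rng)
        self.conv = _ConvModule(d, cfg.pointwise_expansion, cfg.depthwise_kernel, rng)
        self.ffn2 = _FFN(d, cfg.ffn_hidden, rng)
        self.final_norm = nn.LayerNorm(d)
        self.step = 0.5 if cfg.residual_half_step else 1.0

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.step * self.ffn1(x)
        x = x + self.attn(self.attn_norm(x))
        x = x + self.conv(x)
        x = x + self.step * self.ffn2(x)
        return self.final_norm(x)


class _DecoderLayer(nn.Module):
    def __init__(self, in_ch, out_ch, cfg, rng, final: bool):
        super().__init__()
        self.deconv = nn.ConvTranspose1d(
            in_ch, out_ch, cfg.deconv_kernel, stride=cfg.deconv_stride,
            padding=cfg.deconv_padding, output_padding=1, rng=rng,
        )
        self.final = final
        if not final:
            self.bn = nn.BatchNorm1d(out_ch)
        self.slope = cfg.leaky_slope

    def forward(self, x):
        x = self.deconv(x)
        if self.final:
            return x
        return self.bn(x).leaky_relu(self.slope)


class Decoder(nn.Module):
    """Mirrors the encoder; each layer consumes the concatenation of the
    running decoder state and the matching encoder skip (2x channels)."""

    def __init__(self, cfg: TCENVConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.encoder_channels
        outs = (1,) + chans[:-1]  # decoder layer i outputs encoder layer i's input
        for i in reversed(range(cfg.depth)):
            setattr(
                self,
                f"layer{i}",
                _DecoderLayer(2 * chans[i], outs[i], cfg, rng, final=(i == 0)),
            )
        self.depth = cfg.depth

    def forward(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        for i in reversed(range(self.depth)):
            x = Tensor.concat([x, skips[i]], axis=1)
            x = getattr(self, f"layer{i}")(x)
        return x


class TCENV(nn.Module):
    """Full enhancement network; forward maps (B, 1, T) -> (B, 1, T)."""

    def __init__(self, cfg: TCENVConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        if cfg.bottleneck_enabled:
            self.bottleneck = _ConvBNAct(
                cfg.d_model, cfg.d_model, cfg.bottleneck_kernel, 1, 1,
                cfg.leaky_slope, rng,
            )
        for i in range(cfg.n_conformer_layers):
            setattr(self, f"conformer{i}", ConformerBlock(cfg, rng))
        self.decoder = Decoder(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != 1:
            raise ValueError("expected input of shape (batch, 1, T)")
        h, skips = self.encoder(x)
        if self.cfg.bottleneck_enabled:
            h = self.bottleneck(h)
        if self.cfg.n_conformer_layers:
            h = h.transpose(0, 2, 1)  # (B, L, d)
            for i in range(self.cfg.n_conformer_layers):
                h = getattr(self, f"conformer{i}")(h)
            h = h.transpose(0, 2, 1)
        return self.decoder(h, skips)


def build_encoder(cfg: TCENVConfig) -> Encoder:
    return Encoder(cfg, np.random.default_rng(cfg.seed))


def build_conformer_block(cfg: TCENVConfig) -> ConformerBlock:
    return ConformerBlock(cfg, np.random.default_rng(cfg.seed))


def build_tcenv(cfg: TCENVConfig) -> TCENV:
    return TCENV(cfg)


def count_parameters(model: TCENV) -> ParameterCount:
    """Trainable weights/biases per block (running BN stats excluded)."""
    per_block = {"encoder": model.encoder.num_parameters()}
    if model.cfg.bottleneck_enabled:
        per_block["bottleneck"] = model.bottleneck.num_parameters()
    for i in range(model.cfg.n_conformer_layers):
        per_block[f"conformer{i}"] = getattr(model, f"conformer{i}").num_parameters()
    per_block["decoder"] = model.decoder.num_parameters()
    return ParameterCount(total=sum(per_block.values()), per_block=per_block)


def enhance(model: TCENV, noisy: Waveform) -> Waveform:
    """Run the network on a waveform of arbitrary length.

    The input is zero-padded to a multiple of the model's total stride,
    passed through in evaluation mode, and cropped back.
    """
    if len(noisy) < 1:
        raise ValueError("empty input")
    stride = model.cfg.total_stride
    n = len(noisy)
    pad = (-n) % stride
    x = np.concatenate([noisy.samples, np.zeros(pad)]).astype(np.float32)
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            out = model(Tensor(x.reshape(1, 1, -1)))
    finally:
        model.train(was_training)
    return Waveform(out.data.reshape(-1)[:n].astype(np.float64), noisy.sample_rate)
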