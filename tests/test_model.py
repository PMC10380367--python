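"""Architecture contracts: shapes, skips, and exact parameter counts.

The parameter-count oracle below sums each weight tensor's size from the
layer plan symbolically — fully independent of the framework's
``num_parameters`` bookkeeping.
"""

from dataclasses import replace

import numpy as np
import pytest

from tcenv.io_wav import Waveform
from tcenv.model import (
    REFERENCE_CONFIG,
    TCENV,
    TCENVConfig,
    build_conformer_block,
    build_encoder,
    count_parameters,
    enhance,
    tiny_config,
)
from tcenv.nn import Conv1d, Tensor


def oracle_encoder_count(cfg: TCENVConfig) -> int:
    total = 0
    in_ch = 1
    for out in cfg.encoder_channels:
        total += in_ch * out * cfg.conv_kernel + out  # conv weight + bias
        total += 2 * out  # batch-norm affine
        in_ch = out
    return total


def oracle_bottleneck_count(cfg: TCENVConfig) -> int:
    d = cfg.encoder_channels[-1]
    return d * d * cfg.bottleneck_kernel + d + 2 * d


def oracle_conformer_count(cfg: TCENVConfig) -> int:
    d, h = cfg.encoder_channels[-1], cfg.ffn_hidden
    ffn = 2 * d + (d * h + h) + (h * d + d)  # layernorm + two linears
    attn = 2 * d + 4 * (d * d + d)  # layernorm + q/k/v/out projections
    conv = (
        2 * d  # layernorm
        + d * (cfg.pointwise_expansion * d) + cfg.pointwise_expansion * d
        + d * cfg.depthwise_kernel + d  # depthwise (one filter per channel)
        + 2 * d  # batch-norm
        + d * d + d  # second pointwise
    )
    return 2 * ffn + attn + conv + 2 * d  # + final layernorm


def oracle_decoder_count(cfg: TCENVConfig) -> int:
    chans = cfg.encoder_channels
    outs = (1,) + chans[:-1]
    total = 0
    for i in range(len(chans)):
        total += 2 * chans[i] * outs[i] * cfg.deconv_kernel + outs[i]
        if i != 0:  # final layer is a bare transposed conv
            total += 2 * outs[i]
    return total


def oracle_total(cfg: TCENVConfig) -> int:
    total = oracle_encoder_count(cfg) + oracle_decoder_count(cfg)
    if cfg.bottleneck_enabled:
        total += oracle_bottleneck_count(cfg)
    return total + cfg.n_conformer_layers * oracle_conformer_count(cfg)


class TestParameterCounts:
    def test_single_conv_layer_count(self):
        layer = Conv1d(1, 16, 15, rng=np.random.default_rng(0))
        assert layer.num_parameters() == 1 * 16 * 15 + 16 == 256

    @pytest.mark.parametrize("layers", [0, 1, 2])
    def test_framework_count_equals_closed_form_oracle(self, layers):
        cfg = replace(REFERENCE_CONFIG, n_conformer_layers=layers)
        pc = count_parameters(TCENV(cfg))
        assert pc.total == oracle_total(cfg)
        assert sum(pc.per_block.values()) == pc.total

    def test_reference_sizes_match_published_table(self):
        sizes = {}
        for layers in (0, 1, 2):
            cfg = replace(REFERENCE_CONFIG, n_conformer_layers=layers)
            sizes[layers] = count_parameters(TCENV(cfg))
        assert sizes[0].millions == 4.23  # encoder-decoder only
        assert sizes[1].millions == 6.02
        assert sizes[2].millions == 7.81

    def test_adding_a_block_adds_exactly_one_block_count(self):
        one = count_parameters(TCENV(replace(REFERENCE_CONFIG, n_conformer_layers=1)))
        two = count_parameters(TCENV(replace(REFERENCE_CONFIG, n_conformer_layers=2)))
        block = build_conformer_block(REFERENCE_CONFIG).num_parameters()
        assert two.total - one.total == block
        assert block == oracle_conformer_count(REFERENCE_CONFIG)

    def test_tiny_config_also_matches_oracle(self):
        cfg = tiny_config(3)
        assert count_parameters(TCENV(cfg)).total == oracle_total(cfg)


class TestShapes:
    def test_encoder_channel_trace_and_bottleneck_length(self):
        cfg = replace(REFERENCE_CONFIG, n_conformer_layers=0)
        enc = build_encoder(cfg)
        x = Tensor(np.zeros((1, 1, 96000), dtype=np.float32))
        out, skips = enc(x)
        assert out.shape == (1, 256, 375)  # 96000 / 2^8
        assert [s.shape[1] for s in skips] == list(cfg.encoder_channels)

    def test_encoder_minimal_input(self):
        enc = build_encoder(REFERENCE_CONFIG)
        out, _ = enc(Tensor(np.zeros((1, 1, 256), dtype=np.float32)))
        assert out.shape == (1, 256, 1)

    def test_encoder_rejects_indivisible_length(self):
        enc = build_encoder(REFERENCE_CONFIG)
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 1, 100), dtype=np.float32)))

    def test_conformer_block_preserves_shape_and_is_finite(self):
        blk = build_conformer_block(REFERENCE_CONFIG)
        x = Tensor(np.random.default_rng(0).normal(size=(2, 375, 256)).astype(np.float32))
        out = blk(x)
        assert out.shape == (2, 375, 256)
        assert np.all(np.isfinite(out.data))

    def test_full_forward_preserves_length(self):
        model = TCENV(tiny_config(0))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 1, 512)).astype(np.float32))
        assert model(x).shape == (1, 1, 512)

    def test_invalid_head_count_rejected(self):
        with pytest.raises(ValueError):
            replace(REFERENCE_CONFIG, n_heads=7)


class TestEnhance:
    @pytest.mark.parametrize("length", [1000, 4096, 4097])
    def test_output_length_equals_input_length(self, length):
        model = TCENV(tiny_config(0))
        w = Waveform(np.random.default_rng(2).normal(size=length) * 0.1, 8000)
        out = enhance(model, w)
        assert len(out) == length and out.sample_rate == 8000

    def test_untrained_output_is_finite(self):
        model = TCENV(tiny_config(1))
        w = Waveform(np.random.default_rng(3).normal(size=2048) * 0.1, 8000)
        assert np.all(np.isfinite(enhance(model, w).samples))

    def test_eval_mode_is_deterministic(self):
        model = TCENV(tiny_config(2))
        w = Waveform(np.random.default_rng(4).normal(size=2048) * 0.1, 8000)
        a = enhance(model, w)
        b = enhance(model, w)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_weight_init_is_seeded(self):
        a = TCENV(tiny_config(5)).state_dict()
        b = TCENV(tiny_config(5)).state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
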