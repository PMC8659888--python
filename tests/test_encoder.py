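"""Encoder structure: channel bookkeeping, transitions, pyramid pooling,
parameter counting, and the published channel/size schedule."""

import numpy as np
import pytest

from dcnet import nn
from dcnet.config import EncoderConfig
from dcnet.encoder import (
    DenseBlock,
    DenseEncoder,
    DenseLayer,
    PyramidPooling,
    Transition,
    count_parameters,
)
from dcnet.model import DCNet


class TestDenseLayer:
    def test_output_channels_and_size(self):
        layer = DenseLayer(20, 12, dilation=2, drop_rate=0.0,
                           rng=np.random.default_rng(0), bottleneck_width=7)
        y = layer(nn.Tensor(np.zeros((1, 20, 32, 32), dtype=np.float32)))
        assert y.shape == (1, 12, 32, 32)

    def test_growth_rate_one(self):
        layer = DenseLayer(5, 1, dilation=1, drop_rate=0.0,
                           rng=np.random.default_rng(0), bottleneck_width=2)
        y = layer(nn.Tensor(np.zeros((2, 5, 16, 16), dtype=np.float32)))
        assert y.shape[1] == 1


class TestDenseBlock:
    def test_concatenation_channel_arithmetic(self):
        """16 input channels + 12 layers x growth 12 = 160 before transition."""
        cfg = EncoderConfig()
        block = DenseBlock(16, cfg, dilation=1, rng=np.random.default_rng(0))
        assert block.out_channels == 160
        y = block(nn.Tensor(np.zeros((1, 16, 16, 16), dtype=np.float32)))
        assert y.shape == (1, 160, 16, 16)

    def test_single_layer_block(self):
        cfg = EncoderConfig(layers_per_block=1, growth_rate=5,
                            transition_out_channels=(8,) * 5)
        block = DenseBlock(10, cfg, 1, np.random.default_rng(0))
        y = block(nn.Tensor(np.zeros((1, 10, 8, 8), dtype=np.float32)))
        assert y.shape[1] == 15

    def test_sequential_mode_matches_dense_output_channels(self):
        """Without dense connections, the block still emits the channel count
        of the dense block it replaces, so transitions are unchanged."""
        cfg = EncoderConfig(use_dense_connections=False)
        block = DenseBlock(16, cfg, 1, np.random.default_rng(0))
        y = block(nn.Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32)))
        assert y.shape[1] == 160

    def test_dense_mode_concatenates_layer_outputs(self):
        cfg = EncoderConfig(growth_rate=2, layers_per_block=3, drop_rate=0.0,
                            bottleneck_width=2)
        block = DenseBlock(4, cfg, 1, np.random.default_rng(0))
        x = nn.Tensor(np.random.default_rng(1).random((1, 4, 8, 8))
                      .astype(np.float32))
        y = block(x)
        # the first slice of the concatenation is the block input itself
        assert np.array_equal(y.data[:, :4], x.data)


class TestTransition:
    def test_compresses_and_pools(self):
        tr = Transition(160, 80, pool=True, rng=np.random.default_rng(0))
        y = tr(nn.Tensor(np.zeros((1, 160, 64, 64), dtype=np.float32)))
        assert y.shape == (1, 80, 32, 32)

    def test_no_pool_preserves_size(self):
        tr = Transition(32, 16, pool=False, rng=np.random.default_rng(0))
        y = tr(nn.Tensor(np.zeros((1, 32, 17, 17), dtype=np.float32)))
        assert y.shape == (1, 16, 17, 17)

    def test_plain_transition_has_no_batchnorm(self):
        plain = Transition(280, 16, pool=False, rng=np.random.default_rng(0),
                           plain=True)
        assert not hasattr(plain, "bn")
        assert any(p is plain.conv.bias for p in plain.parameters())

    def test_constant_input_average_pool_constant(self):
        tr = Transition(4, 4, pool=True, rng=np.random.default_rng(0))
        tr.eval()
        x = np.full((1, 4, 8, 8), 2.5, dtype=np.float32)
        pooled = tr.pool_op(nn.Tensor(x))
        assert np.allclose(pooled.data, 2.5)


class TestPyramidPooling:
    def test_output_size_matches_input(self):
        ppm = PyramidPooling(16, rng=np.random.default_rng(0))
        y = ppm(nn.Tensor(np.zeros((1, 16, 64, 64), dtype=np.float32)))
        assert y.shape == (1, 16, 64, 64)

    def test_bin1_branch_pools_to_global_mean(self, rng):
        ppm = PyramidPooling(16, rng=np.random.default_rng(0))
        x = nn.Tensor(rng.random((2, 16, 16, 16)).astype(np.float32))
        pooled = ppm.pools[0](x)
        assert np.allclose(pooled.data[..., 0, 0], x.data.mean(axis=(2, 3)),
                           atol=1e-6)

    def test_constant_input_constant_branches(self):
        ppm = PyramidPooling(16, rng=np.random.default_rng(0))
        x = nn.Tensor(np.full((1, 16, 12, 12), 1.5, dtype=np.float32))
        for pool in ppm.pools:
            assert np.allclose(pool(x).data, 1.5)

    def test_input_smaller_than_largest_bin_rejected(self):
        ppm = PyramidPooling(16, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="smaller"):
            ppm(nn.Tensor(np.zeros((1, 16, 4, 4), dtype=np.float32)))


class TestEncoderSchedule:
    def test_default_channel_and_size_schedule(self):
        """The five transitions emit 80/112/118/136/16 channels at sizes
        256/128/64/64/64 for a 256x256 input."""
        enc = DenseEncoder(EncoderConfig(), rng=np.random.default_rng(0))
        enc.eval()
        with nn.no_grad():
            pyr = enc(nn.Tensor(np.zeros((1, 1, 256, 256), dtype=np.float32)))
        assert pyr.channels == (80, 112, 118, 136, 16)
        assert pyr.sizes == (256, 128, 64, 64, 64)
        assert pyr.ppm_out.shape[-2:] == (64, 64)

    def test_four_block_ablation_schedule(self):
        enc = DenseEncoder(EncoderConfig(n_blocks=4),
                           rng=np.random.default_rng(0))
        enc.eval()
        with nn.no_grad():
            pyr = enc(nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert pyr.channels == (80, 112, 118, 136)
        assert len(pyr.levels) == 4

    def test_six_block_ablation_schedule(self):
        enc = DenseEncoder(EncoderConfig(n_blocks=6),
                           rng=np.random.default_rng(0))
        enc.eval()
        with nn.no_grad():
            pyr = enc(nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert pyr.channels[-1] == 140
        assert pyr.sizes[-1] == pyr.sizes[2]  # added block keeps deep size

    def test_sizes_non_increasing(self):
        enc = DenseEncoder(EncoderConfig(), rng=np.random.default_rng(0))
        enc.eval()
        with nn.no_grad():
            pyr = enc(nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert all(a >= b for a, b in zip(pyr.sizes, pyr.sizes[1:]))

    def test_outputs_finite(self, rng):
        enc = DenseEncoder(EncoderConfig(), rng=np.random.default_rng(0))
        enc.eval()
        with nn.no_grad():
            pyr = enc(nn.Tensor(rng.random((1, 1, 64, 64)).astype(np.float32)))
        for level in pyr.levels:
            assert np.all(np.isfinite(level.data))

    def test_wrong_input_shape_rejected(self):
        enc = DenseEncoder(EncoderConfig(), rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible"):
            enc(nn.Tensor(np.zeros((1, 1, 30, 30), dtype=np.float32)))
        with pytest.raises(ValueError, match=r"\(N, 1, H, W\)"):
            enc(nn.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))


class TestCountParameters:
    def test_single_conv_closed_form(self):
        conv = nn.Conv2d(5, 7, 3, bias=True)
        assert count_parameters(conv) == 7 * (5 * 9 + 1)

    def test_default_network_near_quarter_million(self):
        model = DCNet(seed=0)
        n = count_parameters(model)
        assert 0.266e6 <= n <= 0.294e6  # 0.28 M within 5%

    def test_freeze_mask_subtracts_exactly(self):
        model = DCNet(seed=0)
        total = count_parameters(model)
        dec = count_parameters(model.decoder)
        assert count_parameters(model, frozen=model.decoder.parameters()) == (
            total - dec)

    def test_requires_grad_excluded(self):
        conv = nn.Conv2d(2, 2, 1, bias=True)
        conv.weight.requires_grad = False
        assert count_parameters(conv) == 2
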