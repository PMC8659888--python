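import numpy as np
import pytest

from dcnet.config import DecoderConfig, EncoderConfig, PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_encoder_cfg():
    """A miniature five-block encoder for fast structural/gradient tests."""
    return EncoderConfig(
        growth_rate=3, layers_per_block=2, stem_channels=4, bottleneck_width=3,
        transition_out_channels=(6, 5, 4, 4, 4), drop_rate=0.0,
    )


@pytest.fixture
def tiny_decoder_cfg():
    return DecoderConfig(skip_channels=4, fusion_channels=4)


@pytest.fixture
def tiny_model(tiny_encoder_cfg, tiny_decoder_cfg):
    from dcnet.model import DCNet

    return DCNet(tiny_encoder_cfg, tiny_decoder_cfg, seed=7)


@pytest.fixture
def small_phantom_cfg():
    return PhantomConfig(image_size=64, n_pairs=12, seed=5)


def finite_difference_grad(f, param, idx, eps=1e-6):
    """Central finite difference of scalar-valued f at param.data[idx]."""
    old = param.data[idx]
    param.data[idx] = old + eps
    hi = f()
    param.data[idx] = old - eps
    lo = f()
    param.data[idx] = old
    return (hi - lo) / (2 * eps)
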