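"""Densely connected feature encoder with pyramid pooling.

Five dense blocks (growth rate 12, 12 layers each) extract features at
decreasing resolution; a transition (BN+ReLU+Conv1x1, plus 2x2 average
pooling after the first two blocks) compresses channels between blocks to
the fixed schedule (80, 112, 118, 136, 16). The final 16-channel map feeds a
PSPNet-style pyramid pooling module that injects global context at bin sizes
1, 2, 3 and 6.

Each dense layer is a bottleneck: BN+ReLU+Conv1x1 down to a small width,
then BN+ReLU+dilated Conv3x3 producing ``growth_rate`` channels with "same"
zero padding. The bottleneck keeps the full network at roughly 0.28 M
trainable parameters while preserving dense connectivity and the dilated
receptive-field growth; see docs/methods.md for the budget arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .config import EncoderConfig
from .nn.layers import resize_bilinear

__all__ = [
    "DenseLayer",
    "DenseBlock",
    "Transition",
    "PyramidPooling",
    "DenseEncoder",
    "FeaturePyramid",
    "count_parameters",
]


class DenseLayer(nn.Module):
    """BN+ReLU+Conv bottleneck emitting ``growth_rate`` channels.

    With ``bottleneck_width`` set, the layer is Conv1x1 (channel compression)
    followed by a dilated Conv3x3; with ``bottleneck_width=None`` it is a
    single plain Conv3x3 (used by the no-dense-connection ablation blocks).
    Spatial size is always preserved.
    """

    def __init__(self, in_channels: int, growth_rate: int, dilation: int,
                 drop_rate: float, rng, bottleneck_width: int | None = None,
                 dropout_rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = growth_rate
        mods: list[nn.Module] = []
        if bottleneck_width is not None:
            mods += [
                nn.BNReLU(in_channels),
                nn.Conv2d(in_channels, bottleneck_width, 1, rng=rng),
                nn.Dropout(drop_rate, rng=dropout_rng),
                nn.BNReLU(bottleneck_width),
                nn.Conv2d(bottleneck_width, growth_rate, 3, dilation=dilation, rng=rng),
                nn.Dropout(drop_rate, rng=dropout_rng),
            ]
        else:
            mods += [
                nn.BNReLU(in_channels),
                nn.Conv2d(in_channels, growth_rate, 3, dilation=dilation, rng=rng),
                nn.Dropout(drop_rate, rng=dropout_rng),
            ]
        self.body = nn.Sequential(*mods)

    def forward(self, x):
        return self.body(x)


class DenseBlock(nn.Module):
    """A stack of dense layers with (optionally disabled) dense connectivity.

    Dense mode: layer ``k`` consumes the concatenation of the block input and
    all previous layer outputs, and the block returns the full concatenation,
    so output channels = input + layers x growth.  Sequential mode (the
    no-dense-connection ablation): plain 3x3 layers applied in a chain, with
    the last layer widened so the block's output channel count matches the
    dense block it replaces (transitions stay identical).
    """

    def __init__(self, in_channels: int, cfg: EncoderConfig, dilation: int,
                 rng, dropout_rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.dense = cfg.use_dense_connections
        g, L = cfg.growth_rate, cfg.layers_per_block
        self.out_channels = in_channels + L * g
        layers = []
        if self.dense:
            for k in range(L):
                layers.append(DenseLayer(
                    in_channels + k * g, g, dilation, cfg.drop_rate, rng,
                    bottleneck_width=cfg.bottleneck_width, dropout_rng=dropout_rng,
                ))
        else:
            widths = [in_channels] + [g] * (L - 1)
            outs = [g] * (L - 1) + [self.out_channels]
            for w_in, w_out in zip(widths, outs):
                layers.append(DenseLayer(w_in, w_out, dilation, cfg.drop_rate, rng,
                                         bottleneck_width=None,
                                         dropout_rng=dropout_rng))
        self.layers = layers

    def forward(self, x):
        if self.dense:
            feats = [x]
            for layer in self.layers:
                inp = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
                feats.append(layer(inp))
            return nn.concat(feats, axis=1)
        for layer in self.layers:
            x = layer(x)
        return x


class Transition(nn.Module):
    """Channel compression between blocks: BN+ReLU+Conv1x1 (+2x2 avg pool).

    The transition after the last block is a bare convolution (no BN/ReLU).
    """

    def __init__(self, in_channels: int, out_channels: int, pool: bool,
                 rng, plain: bool = False):
        super().__init__()
        self.out_channels = out_channels
        self.pool = pool
        self.plain = plain
        if not plain:
            self.bn = nn.BNReLU(in_channels)
        self.conv = nn.Conv2d(in_channels, out_channels, 1, bias=plain, rng=rng)
        if pool:
            self.pool_op = nn.AvgPool2x2()

    def forward(self, x):
        if not self.plain:
            x = self.bn(x)
        x = self.conv(x)
        if self.pool:
            x = self.pool_op(x)
        return x


class PyramidPooling(nn.Module):
    """PSPNet-style pyramid pooling: parallel adaptive average poolings at
    several bin sizes, 1x1-convolved, upsampled back and concatenated with
    the input, then fused by a BN+ReLU+Conv3x3 to ``out_channels``."""

    def __init__(self, in_channels: int, bins=(1, 2, 3, 6), out_channels: int = 16,
                 rng=None):
        super().__init__()
        self.bins = tuple(bins)
        self.in_channels = in_channels
        self.out_channels = out_channels
        branch_ch = max(in_channels // len(self.bins), 1)
        self.pools = [nn.AdaptiveAvgPool2d(b) for b in self.bins]
        self.branch_convs = [nn.Conv2d(in_channels, branch_ch, 1, rng=rng)
                             for _ in self.bins]
        self.branch_bns = [nn.BNReLU(branch_ch) for _ in self.bins]
        fused_in = in_channels + branch_ch * len(self.bins)
        self.fuse_bn = nn.BNReLU(fused_in)
        self.fuse_conv = nn.Conv2d(fused_in, out_channels, 3, rng=rng)

    def forward(self, x):
        h, w = x.shape[-2:]
        feats = [x]
        for pool, conv, bn in zip(self.pools, self.branch_convs, self.branch_bns):
            b = bn(conv(pool(x)))
            feats.append(resize_bilinear(b, h, w))
        out = nn.concat(feats, axis=1)
        return self.fuse_conv(self.fuse_bn(out))


@dataclass
class FeaturePyramid:
    """Encoder outputs y1..yn (post-transition) plus the pyramid-pooled
    context map."""

    levels: list = field(default_factory=list)
    ppm_out: object = None

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(t.shape[1] for t in self.levels)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(t.shape[-1] for t in self.levels)

    @property
    def deepest(self):
        return self.ppm_out if self.ppm_out is not None else self.levels[-1]


class DenseEncoder(nn.Module):
    """Stem + dense blocks + transitions + optional pyramid pooling."""

    def __init__(self, cfg: EncoderConfig | None = None, rng=None, dropout_rng=None):
        super().__init__()
        self.cfg = cfg = cfg if cfg is not None else EncoderConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stem = nn.Conv2d(1, cfg.stem_channels, 3, rng=rng)
        blocks, transitions = [], []
        c = cfg.stem_channels
        for i in range(cfg.n_blocks):
            block = DenseBlock(c, cfg, cfg.dilation_schedule[i], rng,
                               dropout_rng=dropout_rng)
            blocks.append(block)
            last = i == cfg.n_blocks - 1
            transitions.append(Transition(
                block.out_channels, cfg.transition_out_channels[i],
                pool=False, rng=rng, plain=last,
            ))
            c = cfg.transition_out_channels[i]
        self.blocks = blocks
        self.transitions = transitions
        # downsampling sits between a recorded pyramid level and the next
        # block, so y1/y2 keep their block's resolution (256/128 at 256 input)
        self.pools = [nn.AvgPool2x2() for _ in range(min(2, cfg.n_blocks - 1))]
        if cfg.use_ppm:
            self.ppm = PyramidPooling(c, bins=cfg.ppm_bins, out_channels=16, rng=rng)
        else:
            self.ppm = None

    def forward(self, x) -> FeaturePyramid:
        x = nn.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got shape {x.shape}")
        h, w = x.shape[-2:]
        if h % 4 or w % 4:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 4 (two 2x2 poolings)"
            )
        pyramid = FeaturePyramid()
        feat = self.stem(x)
        for i, (block, trans) in enumerate(zip(self.blocks, self.transitions)):
            level = trans(block(feat))
            pyramid.levels.append(level)
            feat = self.pools[i](level) if i < len(self.pools) else level
        if self.ppm is not None:
            pyramid.ppm_out = self.ppm(pyramid.levels[-1])
        return pyramid


def count_parameters(network: nn.Module, frozen=None) -> int:
    """Total element count of trainable parameter tensors.

    ``frozen`` may be an iterable of Parameters (a freeze mask) to exclude;
    parameters with ``requires_grad`` disabled are always excluded.
    """
    frozen_ids = {id(p) for p in frozen} if frozen is not None else set()
    return sum(
        p.data.size
        for p in network.parameters()
        if p.requires_grad and id(p) not in frozen_ids
    )
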