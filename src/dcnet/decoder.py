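"""Decoder: skip compression, recursive multi-level fusion and mask heads.

Encoder features y1..y(n-1) are compressed to 16 channels by 1x1
convolutions (the modified skip connection), then fused from the deepest
level outwards: each decoder level bilinearly upsamples the previous decoder
feature to the skip's resolution, concatenates, and applies a BN+ReLU+Conv3x3
"activation module". Every level owns a 1-channel head whose logits are
upsampled to the input resolution and passed through a sigmoid, giving the
side outputs S1..S5; their pre-sigmoid logits are concatenated and fused by a
final BN+ReLU+Conv into the overall segmentation S0. Binarisation thresholds
probabilities at 0.5, ties to foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import DecoderConfig, EncoderConfig
from .encoder import FeaturePyramid
from .nn.layers import resize_bilinear

__all__ = ["SkipCompression", "DecoderLevel", "Decoder", "MultiLevelOutput",
           "binarize"]


@dataclass
class MultiLevelOutput:
    """Probability maps S0..Sn at input resolution plus their logits.

    ``probabilities[0]`` is the fused segmentation S0; ``probabilities[k]``
    for k >= 1 is the side output of decoder level k (shallow to deep). All
    maps share the input's spatial size and lie in [0, 1] after the sigmoid.
    """

    probabilities: list
    logits: list

    @property
    def s0(self) -> np.ndarray:
        return np.asarray(self.probabilities[0].data)

    @property
    def n_levels(self) -> int:
        return len(self.probabilities) - 1

    def numpy(self) -> list[np.ndarray]:
        return [np.asarray(p.data) for p in self.probabilities]


def binarize(s, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; S >= threshold maps to foreground."""
    arr = s.data if isinstance(s, nn.Tensor) else np.asarray(s)
    return (arr >= threshold).astype(np.uint8)


class SkipCompression(nn.Module):
    """1x1 convolution compressing an encoder feature to 16 channels."""

    def __init__(self, in_channels: int, out_channels: int = 16, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 1, rng=rng)

    def forward(self, y):
        return self.conv(y)


class DecoderLevel(nn.Module):
    """One decoder stage: upsample previous features, concatenate the skip,
    fuse with BN+ReLU+Conv3x3, and emit a 1-channel logit head."""

    def __init__(self, prev_channels: int, skip_channels: int,
                 fusion_channels: int, rng=None):
        super().__init__()
        in_ch = prev_channels + skip_channels
        self.bn = nn.BNReLU(in_ch)
        self.conv = nn.Conv2d(in_ch, fusion_channels, 3, rng=rng)
        self.head = nn.Conv2d(fusion_channels, 1, 1, bias=True, rng=rng)

    def forward(self, prev, skip=None):
        if skip is not None:
            h, w = skip.shape[-2:]
            prev = resize_bilinear(prev, h, w)
            if prev.shape[-2:] != skip.shape[-2:]:
                raise ValueError("skip/decoder spatial size mismatch")
            prev = nn.concat([prev, skip], axis=1)
        feat = self.conv(self.bn(prev))
        logit = self.head(feat)
        return feat, logit


class Decoder(nn.Module):
    """Full decoder over an encoder pyramid, deepest level seeded by the
    pyramid pooling output (or the last encoder level when PPM is off)."""

    def __init__(self, enc_cfg: EncoderConfig | None = None,
                 dec_cfg: DecoderConfig | None = None, rng=None):
        super().__init__()
        enc_cfg = enc_cfg if enc_cfg is not None else EncoderConfig()
        self.cfg = dec_cfg = dec_cfg if dec_cfg is not None else DecoderConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        n = enc_cfg.n_blocks
        self.n_levels = n
        channels = enc_cfg.transition_out_channels
        deep_ch = 16 if enc_cfg.use_ppm else channels[-1]
        # deepest stage: no skip; bring the context feature to fusion width
        self.deep_bn = nn.BNReLU(deep_ch)
        self.deep_conv = nn.Conv2d(deep_ch, dec_cfg.fusion_channels, 3, rng=rng)
        self.deep_head = nn.Conv2d(dec_cfg.fusion_channels, 1, 1, bias=True, rng=rng)
        if dec_cfg.use_skip:
            self.skips = [SkipCompression(channels[k], dec_cfg.skip_channels, rng=rng)
                          for k in range(n - 1)]
            skip_ch = dec_cfg.skip_channels
        else:
            self.skips = []
            skip_ch = 0
        self.levels = [
            DecoderLevel(dec_cfg.fusion_channels, skip_ch,
                         dec_cfg.fusion_channels, rng=rng)
            for _ in range(n - 1)
        ]
        self.fuse_bn = nn.BNReLU(n)
        self.fuse_conv = nn.Conv2d(n, 1, 3, bias=True, rng=rng)
        for head in [self.deep_head, self.fuse_conv] + [
                lvl.head for lvl in self.levels]:
            head.bias.data[:] = dec_cfg.head_bias_init

    def forward(self, pyramid: FeaturePyramid, out_size: tuple[int, int]
                ) -> MultiLevelOutput:
        h, w = out_size
        # deepest level (S_n): context feature only, no skip
        feat = self.deep_conv(self.deep_bn(pyramid.deepest))
        logits_deep_first = [self.deep_head(feat)]
        for idx in range(self.n_levels - 2, -1, -1):
            level = self.levels[idx]
            if self.cfg.use_skip:
                skip = self.skips[idx](pyramid.levels[idx])
                feat, logit = level(feat, skip)
            else:
                target = pyramid.levels[idx].shape[-2:]
                feat, logit = level(resize_bilinear(feat, *target), None)
            logits_deep_first.append(logit)
        side_logits = [resize_bilinear(l, h, w)
                       for l in reversed(logits_deep_first)]  # S1 .. Sn
        fused = self.fuse_conv(self.fuse_bn(nn.concat(side_logits, axis=1)))
        logits = [fused] + side_logits
        probs = [nn.sigmoid(l) for l in logits]
        return MultiLevelOutput(probabilities=probs, logits=logits)
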