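"""The full segmentation network: dense encoder + multi-level decoder.

``DCNet`` couples the densely connected encoder (with pyramid pooling) to
the skip-compressing, deeply supervised decoder. Ablation variants are
selected by letter:

=======  ==========================================
variant  change relative to the full model (A)
=======  ==========================================
B        pyramid pooling module removed
C        skip connections removed
D        four dense blocks instead of five
E        six dense blocks instead of five
F        single loss on the fused output S0 only
G        dense connectivity inside blocks removed
=======  ==========================================
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import DecoderConfig, EncoderConfig, LossConfig, apply_variant
from .decoder import Decoder, MultiLevelOutput
from .encoder import DenseEncoder

__all__ = ["DCNet"]


class DCNet(nn.Module):
    """Densely connected encoder-decoder for binary tumor segmentation.

    Parameters
    ----------
    encoder_cfg, decoder_cfg
        Architecture settings; defaults reproduce the reference design
        (growth rate 12, 12 layers per block, transition channels
        80/112/118/136/16, skips compressed to 16, PPM bins 1/2/3/6).
    seed
        Seeds both weight initialisation and dropout sampling.
    """

    def __init__(self, encoder_cfg: EncoderConfig | None = None,
                 decoder_cfg: DecoderConfig | None = None, seed: int = 0):
        super().__init__()
        init_rng = np.random.default_rng([seed, 0x5eed])
        self._dropout_rng = np.random.default_rng([seed, 0xd0])
        self.encoder = DenseEncoder(encoder_cfg, rng=init_rng,
                                    dropout_rng=self._dropout_rng)
        self.decoder = Decoder(self.encoder.cfg, decoder_cfg, rng=init_rng)

    @classmethod
    def from_variant(cls, variant: str, seed: int = 0,
                     encoder_cfg: EncoderConfig | None = None,
                     decoder_cfg: DecoderConfig | None = None,
                     loss_cfg: LossConfig | None = None):
        """Build an ablation variant; returns ``(model, loss_config)``."""
        enc, dec, los = apply_variant(variant, encoder_cfg, decoder_cfg, loss_cfg)
        return cls(enc, dec, seed=seed), los

    def reseed_dropout(self, seed: int) -> None:
        """Reset the shared dropout stream (training determinism)."""
        new_rng = np.random.default_rng([seed, 0xd0])
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = new_rng
        self._dropout_rng = new_rng

    def forward(self, x) -> MultiLevelOutput:
        arr = np.asarray(x.data if isinstance(x, nn.Tensor) else x)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        x = nn.as_tensor(arr)
        if x.ndim == 2:
            x = nn.reshape(x, (1, 1) + x.shape)
        elif x.ndim == 3:
            x = nn.reshape(x, (x.shape[0], 1) + x.shape[1:])
        pyramid = self.encoder(x)
        return self.decoder(pyramid, x.shape[-2:])

    def predict_proba(self, images, batch_size: int = 8) -> np.ndarray:
        """Fused probability maps S0 for a stack of slices (eval mode)."""
        was_training = self.training
        self.eval()
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        out = np.empty(
            (len(images), images.shape[-2], images.shape[-1]), dtype=np.float32
        )
        with nn.no_grad():
            for lo in range(0, len(images), batch_size):
                batch = images[lo:lo + batch_size]
                result = self.forward(batch)
                out[lo:lo + len(batch)] = result.s0[:, 0]
        if was_training:
            self.train()
        return out
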