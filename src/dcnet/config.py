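"""Configuration objects for every stage of the pipeline.

All configs are plain dataclasses with validated defaults; ``RunConfig``
composes them and round-trips through YAML with fail-fast rejection of
unknown keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PhantomConfig",
    "EncoderConfig",
    "DecoderConfig",
    "LossConfig",
    "TrainConfig",
    "AugmentConfig",
    "RunConfig",
    "VARIANTS",
    "apply_variant",
]

#: Default transition output channels per number of dense blocks. The
#: five-block schedule is the reference design; four drops the last level,
#: six inserts an extra 140-channel block between the fifth block and the
#: pyramid pooling module.
DEFAULT_TRANSITION_CHANNELS = {
    4: (80, 112, 118, 136),
    5: (80, 112, 118, 136, 16),
    6: (80, 112, 118, 136, 16, 140),
}

#: Dilation factor per dense block: 1 while average pooling still shrinks the
#: grid (blocks 1-2), 2 afterwards to keep enlarging receptive fields.
DEFAULT_DILATIONS = {
    4: (1, 1, 2, 2),
    5: (1, 1, 2, 2, 2),
    6: (1, 1, 2, 2, 2, 2),
}


@dataclass
class PhantomConfig:
    """Synthetic T1-like slice/mask generator settings.

    Foreground area fractions are drawn log-uniformly from
    ``tumor_area_range`` so that tumor scales span orders of magnitude, the
    regime the multi-scale architecture is designed for.
    """

    image_size: int = 256
    n_pairs: int = 100
    tumor_area_range: tuple[float, float] = (0.001, 0.08)
    n_lobes_range: tuple[int, int] = (1, 3)
    foreground_mean: float = 0.75
    foreground_sd: float = 0.06
    background_mean: float = 0.40
    background_amplitude: float = 0.12
    background_smoothness: float = 24.0
    noise_sd: float = 0.03
    boundary_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_area_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(
                f"tumor_area_range must satisfy 0 < min <= max < 0.5, got {self.tumor_area_range}"
            )
        if self.n_lobes_range[0] < 1 or self.n_lobes_range[0] > self.n_lobes_range[1]:
            raise ValueError(f"invalid n_lobes_range {self.n_lobes_range}")
        if self.image_size < 8:
            raise ValueError("image_size too small")


@dataclass
class EncoderConfig:
    """Densely connected encoder settings.

    ``bottleneck_width`` is the channel width of the 1x1 compression in each
    dense layer before its dilated 3x3 convolution; 7 puts the full default
    network at ~0.27 M trainable parameters (see docs/methods.md).
    """

    growth_rate: int = 12
    layers_per_block: int = 12
    n_blocks: int = 5
    drop_rate: float = 0.2
    stem_channels: int = 16
    bottleneck_width: int = 7
    dilation_schedule: tuple[int, ...] | None = None
    transition_out_channels: tuple[int, ...] | None = None
    use_ppm: bool = True
    use_dense_connections: bool = True
    ppm_bins: tuple[int, ...] = (1, 2, 3, 6)

    def __post_init__(self):
        if self.growth_rate < 1 or self.layers_per_block < 1:
            raise ValueError("growth_rate and layers_per_block must be >= 1")
        if self.n_blocks not in (4, 5, 6):
            raise ValueError(f"n_blocks must be 4, 5 or 6, got {self.n_blocks}")
        if self.transition_out_channels is None:
            self.transition_out_channels = DEFAULT_TRANSITION_CHANNELS[self.n_blocks]
        self.transition_out_channels = tuple(self.transition_out_channels)
        if len(self.transition_out_channels) != self.n_blocks:
            raise ValueError(
                "transition_out_channels must have one entry per dense block"
            )
        if self.dilation_schedule is None:
            self.dilation_schedule = DEFAULT_DILATIONS[self.n_blocks]
        self.dilation_schedule = tuple(self.dilation_schedule)
        if len(self.dilation_schedule) != self.n_blocks:
            raise ValueError("dilation_schedule must have one entry per dense block")


@dataclass
class DecoderConfig:
    """Decoder settings: 16-channel skip compression and fusion width.

    ``head_bias_init`` seeds every mask head's bias with a background-prior
    logit (sigmoid(-2) ~ 0.12) so the network starts near the class prior of
    small lesions instead of predicting half the slice as tumor; this is the
    usual prior initialisation for heavily imbalanced dense prediction.
    """

    skip_channels: int = 16
    fusion_channels: int = 16
    use_skip: bool = True
    threshold: float = 0.5
    head_bias_init: float = -2.0

    def __post_init__(self):
        if self.skip_channels < 1 or self.fusion_channels < 1:
            raise ValueError("channel widths must be >= 1")


@dataclass
class LossConfig:
    """Combined weighted-CE + generalized-dice loss settings."""

    lambda_weight: float = 1.0
    epsilon: float = 1e-6
    level_weights: tuple[float, ...] = (1.0,) * 6
    single_loss_mode: bool = False

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        self.level_weights = tuple(self.level_weights)


@dataclass
class AugmentConfig:
    """Stochastic augmentation mix: each transform fires independently."""

    p_rotate: float = 0.5
    p_flip: float = 0.5
    p_translate: float = 0.5
    max_angle_deg: float = 10.0
    max_shift_px: int = 10


@dataclass
class TrainConfig:
    """Three-stage SGD training protocol settings."""

    lr: float = 1e-4
    batch_size: int = 8
    epochs_per_stage: int = 100
    n_stages: int = 3
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    momentum: float = 0.9
    seed: int = 0
    n_cv_trials: int = 4
    variant: str = "A"
    n_train: int = 30
    n_val: int = 10
    augment: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


#: Ablation variants: each maps to the config fields it overrides.
#:   A full model; B no pyramid pooling; C no skip connections; D four dense
#:   blocks; E six dense blocks; F single loss on the fused output only;
#:   G no dense connectivity inside blocks.
VARIANTS = {
    "A": {},
    "B": {"encoder": {"use_ppm": False}},
    "C": {"decoder": {"use_skip": False}},
    "D": {"encoder": {"n_blocks": 4, "transition_out_channels": None,
                      "dilation_schedule": None}},
    "E": {"encoder": {"n_blocks": 6, "transition_out_channels": None,
                      "dilation_schedule": None}},
    "F": {"loss": {"single_loss_mode": True}},
    "G": {"encoder": {"use_dense_connections": False}},
}


def apply_variant(variant: str, encoder: EncoderConfig | None = None,
                  decoder: DecoderConfig | None = None,
                  loss: LossConfig | None = None):
    """Return (encoder, decoder, loss) configs with the variant's overrides."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    enc = dataclasses.replace(encoder) if encoder else EncoderConfig()
    dec = dataclasses.replace(decoder) if decoder else DecoderConfig()
    los = dataclasses.replace(loss) if loss else LossConfig()
    overrides = VARIANTS[variant]
    for target, fields_ in overrides.items():
        obj = {"encoder": enc, "decoder": dec, "loss": los}[target]
        for k, v in fields_.items():
            setattr(obj, k, v)
    enc.__post_init__()
    dec.__post_init__()
    los.__post_init__()
    return enc, dec, los


def _from_mapping(cls, mapping: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {context} config"
        )
    kwargs = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Composite configuration consumed by the command-line interface."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment_params: AugmentConfig = field(default_factory=AugmentConfig)
    data_dir: str | None = None
    out_dir: str | None = None
    log_level: str = "INFO"

    _SECTIONS = {
        "phantom": PhantomConfig,
        "encoder": EncoderConfig,
        "decoder": DecoderConfig,
        "loss": LossConfig,
        "train": TrainConfig,
        "augment_params": AugmentConfig,
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        scalars = {"data_dir", "out_dir", "log_level"}
        unknown = set(raw) - set(cls._SECTIONS) - scalars
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in run config")
        kwargs = {}
        for name, subcls in cls._SECTIONS.items():
            if name in raw:
                kwargs[name] = _from_mapping(subcls, raw[name] or {}, name)
        for name in scalars:
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        doc = {name: plain(getattr(self, name)) for name in self._SECTIONS}
        doc.update(
            data_dir=self.data_dir, out_dir=self.out_dir, log_level=self.log_level
        )
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
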