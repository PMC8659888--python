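"""Three-stage SGD training protocol with plateau learning-rate decay.

The schedule: stage 1 freezes the decoder and trains the encoder, stage 2
freezes the encoder and trains the decoder, stage 3 trains everything. Each
stage runs the same number of epochs with a fresh optimiser and scheduler
(learning rate reset to its initial value). The scheduler multiplies the
learning rate by ``plateau_factor`` whenever the validation Dice coefficient
has not improved for ``plateau_patience`` consecutive epochs. Training is
deterministic under a fixed seed (numpy arithmetic, seeded shuffling,
augmentation and dropout streams).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AugmentConfig, LossConfig, TrainConfig
from .decoder import binarize
from .losses import integrated_loss
from .metrics import dsc
from .model import DCNet
from .phantom import SlicePair
from .preprocess import augment

logger = logging.getLogger(__name__)

__all__ = [
    "split_dataset",
    "freeze",
    "SchedulerState",
    "plateau_step",
    "SGD",
    "train_stage",
    "three_stage_train",
    "cross_validate",
    "evaluate_dsc",
    "TrainResult",
]


def split_dataset(scans, n_train: int = 30, n_val: int = 10, seed: int = 0):
    """Random disjoint train/validation split of the stated sizes."""
    scans = list(scans)
    if len(scans) < n_train + n_val:
        raise ValueError(
            f"need at least {n_train + n_val} scans, got {len(scans)}"
        )
    order = np.random.default_rng([seed, 0x51e]).permutation(len(scans))
    train = [scans[i] for i in order[:n_train]]
    val = [scans[i] for i in order[n_train:n_train + n_val]]
    return train, val


def freeze(network: DCNet, part: str):
    """Exclude a subnetwork's parameters from gradient updates.

    Returns the freeze mask (the list of frozen parameters). Disabling
    ``requires_grad`` also prunes the backward tape, so a frozen encoder
    costs no encoder backprop at all.
    """
    for p in network.parameters():
        p.requires_grad = True
    if part == "none":
        return []
    if part == "encoder":
        frozen = network.encoder.parameters()
    elif part == "decoder":
        frozen = network.decoder.parameters()
    else:
        raise ValueError(f"unknown part {part!r}: use encoder/decoder/none")
    for p in frozen:
        p.requires_grad = False
    return frozen


@dataclass
class SchedulerState:
    """Plateau scheduler: decay lr after ``patience`` non-improving epochs."""

    current_lr: float
    patience: int = 10
    factor: float = 0.1
    best_val_dsc: float = -np.inf
    epochs_since_improvement: int = 0


def plateau_step(state: SchedulerState, val_dsc: float) -> SchedulerState:
    """Advance the scheduler by one epoch of validation DSC."""
    if not np.isfinite(val_dsc):
        raise ValueError("validation DSC must be finite")
    if val_dsc > state.best_val_dsc:
        state.best_val_dsc = val_dsc
        state.epochs_since_improvement = 0
    else:
        state.epochs_since_improvement += 1
        if state.epochs_since_improvement >= state.patience:
            state.current_lr *= state.factor
            state.epochs_since_improvement = 0
            logger.info("plateau: lr decayed to %.2e", state.current_lr)
    return state


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if not p.requires_grad or p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict
    best_val_dsc: float

    def restore_best(self, model: DCNet) -> None:
        model.load_state_dict(self.best_state)


def evaluate_dsc(model: DCNet, images: np.ndarray, masks: np.ndarray,
                 batch_size: int = 8, threshold: float = 0.5) -> float:
    """Mean Dice of thresholded fused outputs over an evaluation set."""
    probs = model.predict_proba(images, batch_size=batch_size)
    scores = [dsc(binarize(p, threshold), m) for p, m in zip(probs, masks)]
    return float(np.mean(scores))


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


_STAGE_FREEZE = {1: "decoder", 2: "encoder", 3: "none"}


def train_stage(model: DCNet, train_images, train_masks, val_images, val_masks,
                cfg: TrainConfig, loss_cfg: LossConfig, stage: int,
                augment_params: AugmentConfig | None = None,
                epoch_offset: int = 0) -> list[dict]:
    """Run one training stage; returns per-epoch history records."""
    if stage not in _STAGE_FREEZE:
        raise ValueError(f"stage must be 1, 2 or 3, got {stage}")
    if len(train_images) == 0:
        raise ValueError("empty training set")
    freeze(model, _STAGE_FREEZE[stage])
    optimizer = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum)
    sched = SchedulerState(current_lr=cfg.lr, patience=cfg.plateau_patience,
                           factor=cfg.plateau_factor)
    rng = np.random.default_rng([cfg.seed, stage, 0xba7c])
    aug_rng = np.random.default_rng([cfg.seed, stage, 0xa06])
    history = []
    n_levels = None
    for epoch in range(cfg.epochs_per_stage):
        model.train()
        optimizer.lr = sched.current_lr
        losses, level_sums = [], None
        for batch_idx in _epoch_batches(len(train_images), cfg.batch_size, rng):
            if cfg.augment:
                pairs = [augment(SlicePair(train_images[i], train_masks[i]),
                                 aug_rng, augment_params) for i in batch_idx]
                xb = np.stack([p.image for p in pairs])[:, None]
                gb = np.stack([p.mask for p in pairs])[:, None]
            else:
                xb = train_images[batch_idx][:, None]
                gb = train_masks[batch_idx][:, None]
            out = model(xb)
            loss, levels = integrated_loss(out, gb.astype(np.float32), loss_cfg,
                                           return_levels=True)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            level_sums = (np.array(levels) if level_sums is None
                          else level_sums + np.array(levels))
            n_levels = len(levels)
        val_dsc = evaluate_dsc(model, val_images, val_masks, cfg.batch_size)
        record = {
            "epoch": epoch_offset + epoch,
            "stage": stage,
            "lr": sched.current_lr,
            "train_loss": float(np.mean(losses)),
            "val_dsc": val_dsc,
        }
        n_batches = len(losses)
        for k in range(n_levels):
            record[f"J{k}"] = float(level_sums[k] / n_batches)
        history.append(record)
        plateau_step(sched, val_dsc)
    return history


def three_stage_train(model: DCNet, train_images, train_masks, val_images,
                      val_masks, cfg: TrainConfig,
                      loss_cfg: LossConfig | None = None,
                      augment_params: AugmentConfig | None = None) -> TrainResult:
    """Run the full staged protocol, retaining the best-validation state."""
    loss_cfg = loss_cfg if loss_cfg is not None else LossConfig()
    model.reseed_dropout(cfg.seed)
    records = []
    best_dsc, best_state = -np.inf, None
    offset = 0
    for stage in range(1, cfg.n_stages + 1):
        stage_hist = train_stage(model, train_images, train_masks, val_images,
                                 val_masks, cfg, loss_cfg, stage,
                                 augment_params, epoch_offset=offset)
        offset += len(stage_hist)
        for rec in stage_hist:
            if rec["val_dsc"] > best_dsc:
                best_dsc = rec["val_dsc"]
                best_state = model.state_dict()
        records.extend(stage_hist)
    freeze(model, "none")
    if best_state is None:
        best_state = model.state_dict()
    return TrainResult(history=pd.DataFrame(records), best_state=best_state,
                       best_val_dsc=float(best_dsc))


def cross_validate(images, masks, cfg: TrainConfig,
                   loss_cfg: LossConfig | None = None,
                   n_train: int | None = None, n_val: int | None = None):
    """Independent resplit-and-train trials; returns per-trial mean DSC."""
    if cfg.n_cv_trials < 2:
        raise ValueError("n_cv_trials must be >= 2")
    n_train = n_train if n_train is not None else cfg.n_train
    n_val = n_val if n_val is not None else cfg.n_val
    scores = []
    for trial in range(cfg.n_cv_trials):
        trial_seed = int(np.random.default_rng([cfg.seed, trial]).integers(2 ** 31))
        idx_train, idx_val = split_dataset(range(len(images)), n_train, n_val,
                                           seed=trial_seed)
        model, trial_loss_cfg = DCNet.from_variant(cfg.variant, seed=trial_seed,
                                                   loss_cfg=loss_cfg)
        trial_cfg = TrainConfig(**{**cfg.__dict__, "seed": trial_seed})
        result = three_stage_train(
            model, images[idx_train], masks[idx_train],
            images[idx_val], masks[idx_val], trial_cfg, trial_loss_cfg,
        )
        result.restore_best(model)
        scores.append(evaluate_dsc(model, images[idx_val], masks[idx_val],
                                   cfg.batch_size))
    return scores
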