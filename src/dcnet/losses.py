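"""Segmentation losses: class-imbalance-weighted cross entropy, generalized
dice, their sum, and the multi-level integrated loss.

Per slice with ground truth G (binary) and predicted probabilities P:

* weighted CE = -[ lambda * omega * sum(G log P) + sum((1-G) log(1-P)) ] / V,
  where V is the pixel count of the slice and omega = (V - V_P1) / V_P1 with
  V_P1 the soft predicted tumor area (sum of P). omega is the
  background-to-foreground ratio, boosting the minority tumor class; it is
  treated as a constant during gradient computation and V_P1 is clamped from
  below for stability.
* generalized dice = 1 - 2 (w1 |P1 n G1| + w0 |P0 n G0|)
  / (w1 (|P1|+|G1|) + w0 (|P0|+|G0|)), with P1 = P, P0 = 1-P (and likewise
  for G) and class weights w1 = 1/|G1|, w0 = 1/|G0| (epsilon-stabilised when
  a class is absent). Intersections are soft sums of products.

The integrated loss sums the combined loss over every output level S0..Sn
(deep supervision); the single-loss ablation instead returns
(n+1) * J(S0), matching the supervision budget of the full objective.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .config import LossConfig
from .decoder import MultiLevelOutput

logger = logging.getLogger(__name__)

_warned_degenerate = False

__all__ = [
    "weighted_ce",
    "generalized_dice_loss",
    "combined_loss",
    "integrated_loss",
]


def _flatten(P, G):
    """Coerce to (n_slices, n_pixels); validate shapes and P's range."""
    P = nn.as_tensor(P)
    G_arr = np.asarray(G.data if isinstance(G, nn.Tensor) else G, dtype=P.dtype)
    if P.shape != G_arr.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs G {G_arr.shape}")
    if float(P.data.min()) < 0.0 or float(P.data.max()) > 1.0:
        raise ValueError("probability map P has values outside [0, 1]")
    if P.ndim <= 1:
        n, v = 1, P.data.size
    elif P.ndim == 2:
        n, v = 1, P.data.size
    else:  # (N, 1, H, W) or (N, H, W): leading axis indexes slices
        n = P.shape[0]
        v = P.data.size // n
    return nn.reshape(P, (n, v)), G_arr.reshape(n, v), v


def weighted_ce(P, G, cfg: LossConfig | None = None) -> nn.Tensor:
    """Pixel-wise weighted cross entropy, averaged over the batch."""
    cfg = cfg if cfg is not None else LossConfig()
    P, G, v = _flatten(P, G)
    eps = cfg.epsilon
    Pc = nn.clamp(P, eps, 1.0 - eps)
    # foreground weight from the soft predicted area; constant w.r.t. gradients
    vp1 = np.maximum(P.data.sum(axis=1), eps * v)
    omega = (v - vp1) / vp1
    fg = nn.tsum(nn.log(Pc) * G, axis=1)
    bg = nn.tsum(nn.log(1.0 - Pc) * (1.0 - G), axis=1)
    per_slice = -(cfg.lambda_weight * omega * fg + bg) * (1.0 / v)
    return nn.tmean(per_slice)


def generalized_dice_loss(P, G, epsilon: float = 1e-6) -> nn.Tensor:
    """Generalized (two-class, inverse-area-weighted) dice loss in [0, 1]."""
    P, G, v = _flatten(P, G)
    g1 = G.sum(axis=1)
    g0 = v - g1
    if np.any(g1 == 0) or np.any(g0 == 0):
        # common under augmentation of tiny lesions; warn once, then debug
        global _warned_degenerate
        level = logging.DEBUG if _warned_degenerate else logging.WARNING
        _warned_degenerate = True
        logger.log(
            level,
            "all-background or all-foreground ground truth: "
            "epsilon-stabilised dice weights in use",
        )
    eps_abs = epsilon * v
    w1 = 1.0 / np.maximum(g1, eps_abs)
    w0 = 1.0 / np.maximum(g0, eps_abs)
    inter1 = nn.tsum(P * G, axis=1)
    inter0 = nn.tsum((1.0 - P) * (1.0 - G), axis=1)
    p1 = nn.tsum(P, axis=1)
    p0 = v - p1
    num = 2.0 * (w1 * inter1 + w0 * inter0)
    den = w1 * (p1 + g1) + w0 * (p0 + g0)
    return nn.tmean(1.0 - num / den)


def combined_loss(P, G, cfg: LossConfig | None = None) -> nn.Tensor:
    """J(P) = CE(P) + DL(P)."""
    cfg = cfg if cfg is not None else LossConfig()
    return weighted_ce(P, G, cfg) + generalized_dice_loss(P, G, cfg.epsilon)


def integrated_loss(out: MultiLevelOutput, G, cfg: LossConfig | None = None,
                    return_levels: bool = False):
    """Deep-supervision objective: sum of combined losses over S0..Sn.

    In ``single_loss_mode`` only the fused output is supervised, scaled by
    the number of levels so the total loss magnitude is comparable.
    """
    cfg = cfg if cfg is not None else LossConfig()
    n_maps = len(out.probabilities)
    if cfg.single_loss_mode:
        j0 = combined_loss(out.probabilities[0], G, cfg)
        total = float(n_maps) * j0
        levels = [j0.item()] + [np.nan] * (n_maps - 1)
        return (total, levels) if return_levels else total
    total = None
    levels = []
    for k, s in enumerate(out.probabilities):
        wk = cfg.level_weights[k] if k < len(cfg.level_weights) else 1.0
        jk = combined_loss(s, G, cfg)
        levels.append(jk.item())
        term = wk * jk
        total = term if total is None else total + term
    return (total, levels) if return_levels else total
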