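"""Fused elementwise kernels for batch normalisation (numba-JIT).

Batch-norm forward/backward dominate a training step when written as chains
of numpy broadcasts (each an extra pass over activation memory). These
kernels fuse them into single passes; ``layers.py`` falls back to numpy
expressions when numba is unavailable. Inner loops accumulate in the input
precision (SIMD-friendly) per row and promote to float64 per channel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "channel_stats",
    "affine_relu_fwd",
    "bn_bwd_reduce",
    "bn_bwd_apply",
]


@njit(cache=True, fastmath=True)
def channel_stats(x):
    """Per-channel sum and sum of squares of an (N, C, S) array."""
    n, c, s = x.shape
    sums = np.zeros(c, dtype=np.float64)
    sqs = np.zeros(c, dtype=np.float64)
    zero = x.dtype.type(0.0)
    for i in range(n):
        for j in range(c):
            acc = zero
            acc2 = zero
            row = x[i, j]
            for k in range(s):
                v = row[k]
                acc += v
                acc2 += v * v
            sums[j] += acc
            sqs[j] += acc2
    return sums, sqs


@njit(cache=True, fastmath=True)
def affine_relu_fwd(x, a, b, apply_relu):
    """out = a[c] * x + b[c], optionally clamped at zero (fused BN+ReLU)."""
    n, c, s = x.shape
    out = np.empty_like(x)
    for i in range(n):
        for j in range(c):
            aj = x.dtype.type(a[j])
            bj = x.dtype.type(b[j])
            row = x[i, j]
            orow = out[i, j]
            if apply_relu:
                for k in range(s):
                    v = aj * row[k] + bj
                    orow[k] = v if v > 0 else 0
            else:
                for k in range(s):
                    orow[k] = aj * row[k] + bj
    return out


@njit(cache=True, fastmath=True)
def bn_bwd_reduce(g, out, x, masked):
    """Mask g by the ReLU (in place, when ``masked``) and return the
    per-channel sums of g and g*x needed by the batch-norm backward pass."""
    n, c, s = g.shape
    sum_g = np.zeros(c, dtype=np.float64)
    sum_gx = np.zeros(c, dtype=np.float64)
    zero = g.dtype.type(0.0)
    for i in range(n):
        for j in range(c):
            grow = g[i, j]
            orow = out[i, j]
            xrow = x[i, j]
            accg = zero
            accgx = zero
            if masked:
                for k in range(s):
                    gv = grow[k] if orow[k] > 0 else zero
                    grow[k] = gv
                    accg += gv
                    accgx += gv * xrow[k]
            else:
                for k in range(s):
                    gv = grow[k]
                    accg += gv
                    accgx += gv * xrow[k]
            sum_g[j] += accg
            sum_gx[j] += accgx
    return sum_g, sum_gx


@njit(cache=True, fastmath=True)
def bn_bwd_apply(gm, x, a1, b1, c1):
    """gx = gm * a1[c] + x * b1[c] + c1[c], written in place into gm."""
    n, c, s = gm.shape
    for i in range(n):
        for j in range(c):
            aj = gm.dtype.type(a1[j])
            bj = gm.dtype.type(b1[j])
            cj = gm.dtype.type(c1[j])
            grow = gm[i, j]
            xrow = x[i, j]
            for k in range(s):
                grow[k] = grow[k] * aj + xrow[k] * bj + cj
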