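"""Evaluation metrics for binary segmentation and the exact Mann-Whitney U
test used to compare cross-validation DSC samples.

All overlap metrics operate on binary masks P (prediction) and G (ground
truth): DSC = 2|P∩G|/(|P|+|G|), SEN = |P∩G|/|G|, SPE = TN/|not G|,
PPV = |P∩G|/|P|, VOE = 1 - Jaccard, RVD = (|P|-|G|)/|G|. Degenerate
denominators follow declared conventions (see each function) so batch
evaluation is total; undefined values are returned as NaN and excluded from
aggregate means with a count of exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "dsc", "sen", "spe", "ppv", "voe", "rvd",
    "mann_whitney_exact", "evaluate", "MetricsReport", "METRIC_NAMES",
]

METRIC_NAMES = ("dsc", "sen", "spe", "ppv", "voe", "rvd")


def _counts(P, G):
    P = np.asarray(P).astype(bool)
    G = np.asarray(G).astype(bool)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    inter = int(np.count_nonzero(P & G))
    return P, G, inter, int(P.sum()), int(G.sum()), P.size


def dsc(P, G, printed_formula: bool = False) -> float:
    """Dice similarity coefficient 2|P∩G|/(|P|+|G|).

    ``printed_formula=True`` drops the factor 2 (an audit variant of a
    non-standard rendering of the definition). Two empty masks give 1.0.
    """
    _, _, inter, p, g, _ = _counts(P, G)
    if p + g == 0:
        logger.warning("dsc: both masks empty, defined as 1.0")
        return 1.0
    num = inter if printed_formula else 2 * inter
    return num / (p + g)


def sen(P, G) -> float:
    """Sensitivity |P∩G|/|G| (tumor fraction detected); NaN if G is empty."""
    _, _, inter, _, g, _ = _counts(P, G)
    if g == 0:
        return float("nan")
    return inter / g


def spe(P, G) -> float:
    """Specificity: true negatives over ground-truth negatives; NaN if G
    covers the whole slice."""
    Pb, Gb, _, _, g, n = _counts(P, G)
    if n - g == 0:
        return float("nan")
    tn = int(np.count_nonzero(~(Pb | Gb)))
    return tn / (n - g)


def ppv(P, G) -> float:
    """Positive predictive value |P∩G|/|P|; NaN if P is empty."""
    _, _, inter, p, _, _ = _counts(P, G)
    if p == 0:
        return float("nan")
    return inter / p


def voe(P, G) -> float:
    """Volumetric overlap error 1 - |P∩G|/|P∪G|; two empty masks give 0."""
    _, _, inter, p, g, _ = _counts(P, G)
    union = p + g - inter
    if union == 0:
        logger.warning("voe: both masks empty, defined as 0.0")
        return 0.0
    return 1.0 - inter / union


def rvd(P, G) -> float:
    """Relative volume difference (|P|-|G|)/|G|; NaN if G is empty."""
    _, _, _, p, g, _ = _counts(P, G)
    if g == 0:
        return float("nan")
    return (p - g) / g


def mann_whitney_exact(a, b) -> float:
    """Exact two-sided Mann-Whitney U p-value by complete enumeration.

    Enumerates all C(n+m, n) assignments of the pooled sample to the two
    groups and counts those whose U statistic (mid-rank convention for ties)
    is at least as far from its null mean nm/2 as the observed one. Intended
    for the small samples of per-trial cross-validation scores (n, m <= 12).
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    n, m = len(a), len(b)
    if n > 12 or m > 12:
        raise ValueError("exact enumeration supports at most 12 per group")
    pooled = np.asarray(a + b)
    ranks = rankdata(pooled)  # mid-ranks for ties
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    d_obs = abs(u_obs - mu)
    total = comb(n + m, n)
    count = 0
    idx_all = range(n + m)
    tol = 1e-9
    for group in combinations(idx_all, n):
        u = ranks[list(group)].sum() - n * (n + 1) / 2.0
        if abs(u - mu) >= d_obs - tol:
            count += 1
    return count / total


@dataclass
class MetricsReport:
    """Per-pair metric table plus aggregate means and exclusion counts."""

    per_pair: pd.DataFrame
    means: dict
    n_excluded: dict

    def to_csv(self, path) -> None:
        self.per_pair.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        doc = {
            "means": {k: (None if np.isnan(v) else float(v))
                      for k, v in self.means.items()},
            "n_excluded": self.n_excluded,
            "n_pairs": int(len(self.per_pair)),
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def _read_mask(path: Path) -> np.ndarray:
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).get_fdata())
    else:
        arr = np.asarray(Image.open(path))
    return (arr > (arr.max() / 2.0 if arr.max() > 1 else 0)).astype(np.uint8)


def compute_all(P, G) -> dict:
    """All six metrics for one mask pair."""
    return {
        "dsc": dsc(P, G), "sen": sen(P, G), "spe": spe(P, G),
        "ppv": ppv(P, G), "voe": voe(P, G), "rvd": rvd(P, G),
    }


def evaluate(pred_dir, gt_dir) -> MetricsReport:
    """Evaluate same-named mask files of two directories against each other."""
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    exts = ("*.png", "*.nii", "*.nii.gz")
    preds = {p.name: p for ext in exts for p in pred_dir.glob(ext)}
    gts = {p.name: p for ext in exts for p in gt_dir.glob(ext)}
    orphans = sorted(set(preds) ^ set(gts))
    if orphans:
        raise ValueError(f"unpaired mask file(s): {orphans}")
    if not preds:
        raise ValueError(f"no mask files found in {pred_dir} / {gt_dir}")
    rows = []
    for name in sorted(preds):
        P = _read_mask(preds[name])
        G = _read_mask(gts[name])
        rows.append({"name": name, **compute_all(P, G)})
    table = pd.DataFrame(rows)
    means, excl = {}, {}
    for metric in METRIC_NAMES:
        col = table[metric]
        excl[metric] = int(col.isna().sum())
        means[metric] = float(col.mean())  # pandas mean skips NaN
    return MetricsReport(per_pair=table, means=means, n_excluded=excl)


def compare_reports(a: MetricsReport, b: MetricsReport) -> dict:
    """Per-metric exact Mann-Whitney p-values between two reports."""
    out = {}
    for metric in METRIC_NAMES:
        x = a.per_pair[metric].dropna().tolist()
        y = b.per_pair[metric].dropna().tolist()
        if x and y and len(x) <= 12 and len(y) <= 12:
            out[metric] = mann_whitney_exact(x, y)
        else:
            out[metric] = float("nan")
    return out
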