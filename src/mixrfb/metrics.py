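"""Performance metric primitives: AUC, F1 and percentile intervals."""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["compute_auc", "compute_f1", "percentile_ci"]


def compute_auc(scores, labels) -> float:
    """Mann-Whitney concordance: (wins + 0.5 * ties) / (n_pos * n_neg).

    Computed from midranks, which is algebraically identical to averaging
    over all positive-negative pairs with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both outcome classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def compute_f1(scores, labels, threshold: float = 0.5) -> float:
    """F1 for the positive (death) class; prediction is score >= threshold.

    Returns 0 when precision + recall is 0 (no predicted positives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if (labels == 1).sum() == 0:
        raise ValueError("F1 undefined: no positive labels")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval with the linear-interpolation convention."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("percentile_ci needs at least 2 finite values")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)],
                           method="linear")
    return float(lo), float(hi)
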