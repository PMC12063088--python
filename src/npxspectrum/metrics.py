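"""Shared rank-based metrics."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc"]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney concordance; ties get half credit).

    ``labels`` are binary with 1 = positive class. Equals U / (n1 * n0).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
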