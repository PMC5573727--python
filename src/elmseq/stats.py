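"""Small statistical utilities shared across modules."""

from __future__ import annotations

import numpy as np


def bonferroni(p_values, n_tests: int | None = None):
    """Bonferroni correction: multiply by the number of tests, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(p * m, 1.0)


def rank_auc(labels, scores) -> float:
    """Area under the ROC curve via the rank-sum identity; ties count 1/2.

    ``labels`` are binary (1/True = positive class).
    """
    from scipy.stats import rankdata

    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
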