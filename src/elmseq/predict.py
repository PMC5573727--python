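"""Sequence-based predictors of expression class and DAMRatio.

Sequences are one-hot encoded (A=(1,0,0,0), C=(0,1,0,0), G=(0,0,1,0),
T=(0,0,0,1), concatenated per position). A Bernoulli naive Bayes
classifier scores the independent per-base contributions to the high/low
class, and an epsilon-insensitive support vector regression (RBF kernel,
epsilon = 0.2 on log10 DAMRatio) gives the quantitative predictor.
Folding-energy features can be appended for windows whose training-split
dG-expression correlation is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVR

from .stats import rank_auc as auc  # re-exported: rank AUC with ties at 1/2

BASES = "ACGT"
_ONE_HOT = {b: tuple(int(i == k) for i in range(4)) for k, b in enumerate(BASES)}

__all__ = [
    "one_hot", "one_hot_matrix", "decode_one_hot", "auc",
    "train_nb", "predict_nb", "train_svr", "predict_svr", "build_features",
]


def one_hot(seq: str) -> np.ndarray:
    """Concatenated per-position 4-vectors for one sequence."""
    try:
        return np.array(
            [bit for base in seq for bit in _ONE_HOT[base]], dtype=np.int8
        )
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r}") from None


def one_hot_matrix(seqs) -> np.ndarray:
    return np.stack([one_hot(s) for s in seqs])


def decode_one_hot(row: np.ndarray) -> str:
    blocks = np.asarray(row).reshape(-1, 4)
    if not np.all(blocks.sum(axis=1) == 1):
        raise ValueError("each 4-block must contain exactly one 1")
    return "".join(BASES[int(np.argmax(b))] for b in blocks)


@dataclass
class NBModel:
    clf: BernoulliNB
    feature_count: int

    def to_metadata(self) -> dict:
        return {"kind": "naive_bayes", "event_model": "bernoulli",
                "alpha": 1.0, "n_features": self.feature_count}


@dataclass
class SVRModel:
    reg: SVR
    feature_count: int
    epsilon: float
    c: float
    dg_windows: list = field(default_factory=list)
    train_pearson_r: float = float("nan")

    def to_metadata(self) -> dict:
        return {
            "kind": "svr", "kernel": "rbf", "epsilon": self.epsilon,
            "C": self.c, "n_features": self.feature_count,
            "dg_windows": self.dg_windows,
            "train_pearson_r": self.train_pearson_r,
        }


def train_nb(encoded: np.ndarray, labels) -> NBModel:
    """Bernoulli naive Bayes (Laplace smoothing 1) on binary features."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = BernoulliNB(alpha=1.0)
    clf.fit(encoded, y)
    return NBModel(clf=clf, feature_count=encoded.shape[1])


def predict_nb(model: NBModel, encoded: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive ("high") class."""
    classes = list(model.clf.classes_)
    positive = _positive_class(classes)
    return model.clf.predict_proba(encoded)[:, classes.index(positive)]


def _positive_class(classes):
    for candidate in ("high", 1, True):
        if candidate in classes:
            return candidate
    return classes[-1]


def train_svr(
    features: np.ndarray,
    y,
    epsilon: float = 0.2,
    c: float = 1.0,
    kernel: str = "rbf",
    gamma="auto",
) -> SVRModel:
    """Epsilon-insensitive SVR on log10 DAMRatio; deterministic fit.

    gamma="auto" sets the RBF bandwidth to 1 / n_features.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 50:
        raise ValueError("SVR training needs at least 50 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite targets")
    if np.std(y) == 0:
        raise ValueError("constant target: nothing to regress")
    reg = SVR(kernel=kernel, epsilon=epsilon, C=c, gamma=gamma)
    reg.fit(features, y)
    pred = reg.predict(features)
    return SVRModel(
        reg=reg,
        feature_count=features.shape[1],
        epsilon=epsilon,
        c=c,
        train_pearson_r=float(np.corrcoef(pred, y)[0, 1]),
    )


def predict_svr(model: SVRModel, features: np.ndarray) -> np.ndarray:
    if features.shape[1] != model.feature_count:
        raise ValueError("feature count mismatch with the trained model")
    return model.reg.predict(features)


def build_features(
    variants,
    fold_scan,
    provider,
    mrnas=None,
    utr_length: int = 26,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One-hot features plus dG columns for positively correlated windows.

    ``fold_scan`` must come from the training split only (its selected
    windows are frozen into the model metadata). Windows with r > 0 each
    contribute one dG feature column; when none qualifies the plain one-hot
    matrix is returned with a warning.
    """
    import warnings

    X = one_hot_matrix(variants).astype(float)
    table = fold_scan.table if hasattr(fold_scan, "table") else fold_scan
    selected = [
        (int(row.start), int(row.end))
        for row in table.dropna(subset=["r"]).itertuples()
        if row.r > 0
    ]
    if not selected:
        warnings.warn("no folding window with r > 0; using sequence-only features")
        return X, []
    if mrnas is None:
        raise ValueError("mrnas required to compute dG features")

    def to_index(coord: int) -> int:
        return utr_length + coord if coord < 0 else utr_length + coord - 1

    cols = []
    for start, end in selected:
        i0, i1 = to_index(start), to_index(end) + 1
        cols.append(provider.fold_many([m[i0:i1] for m in mrnas]))
    return np.hstack([X, np.stack(cols, axis=1)]), selected
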