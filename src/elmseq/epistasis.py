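"""Pairwise positional epistasis from mutual information (MI).

The plug-in MI between the bases at two positions of the high-productive
set measures how strongly the positions co-vary among active sequences.
Random libraries have a nonzero baseline MI (finite-sample bias plus any
synthesis bias), so epistasis is scored as the ratio of the observed MI to
the mean MI of repeated random draws of the same size from the full
library. Ratios near 1 mean no epistasis beyond library structure.

MI is reported in bits; ratios are unit-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def encode_sequences(seqs) -> np.ndarray:
    """Sequences -> (n, L) uint8 matrix with A,C,G,T -> 0..3."""
    if isinstance(seqs, np.ndarray):
        return seqs
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    L = len(seqs[0])
    arr = arr.reshape(len(seqs), L)
    out = np.zeros_like(arr)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits of an explicit (4, 4) joint count/probability table."""
    p = np.asarray(joint, dtype=float)
    p = p / p.sum()
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pj))
    return float(np.nansum(terms))


def mi_pair(seqs, i: int, j: int) -> float:
    """Plug-in MI (bits) between the bases at positions i and j."""
    m = encode_sequences(seqs)
    if i == j:
        raise ValueError("MI of a position with itself is excluded")
    code = m[:, i].astype(np.int64) * 4 + m[:, j]
    joint = np.bincount(code, minlength=16).reshape(4, 4)
    return mi_from_joint(joint)


def mi_matrix(seqs) -> np.ndarray:
    """All-pairs MI matrix (bits); diagonal is NaN."""
    m = encode_sequences(seqs)
    L = m.shape[1]
    out = np.full((L, L), np.nan)
    cols = m.astype(np.int64)
    for i in range(L):
        for j in range(i + 1, L):
            code = cols[:, i] * 4 + cols[:, j]
            joint = np.bincount(code, minlength=16).reshape(4, 4)
            out[i, j] = out[j, i] = mi_from_joint(joint)
    return out


def mi_null(
    pool,
    n_draws: int = 10_000,
    draw_size: int = 10_000,
    seed: int = 0,
    replace: bool = False,
) -> np.ndarray:
    """Mean all-pairs MI over random subsets of the library pool.

    Draws ``n_draws`` subsets of ``draw_size`` sequences (without
    replacement within a draw by default) and averages their MI matrices.
    Deterministic for a given seed.
    """
    pool_m = encode_sequences(pool)
    n = pool_m.shape[0]
    if draw_size > n:
        raise ValueError(f"draw_size {draw_size} exceeds pool size {n}")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_draws):
        idx = rng.choice(n, size=draw_size, replace=replace)
        mat = mi_matrix(pool_m[idx])
        acc = mat if acc is None else acc + mat
    return acc / n_draws


def epistasis_ratio(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Elementwise MI(observed) / MI(null mean); NaN where the null is zero."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.shape != null.shape:
        raise ValueError("observed and null matrices must share shape")
    zero = null == 0
    if np.any(zero & np.isfinite(observed)):
        warnings.warn("null MI of 0 for some pairs; ratio reported as NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed / null
    ratio[zero] = np.nan
    return ratio


@dataclass
class EpistasisResult:
    mi_observed: np.ndarray
    mi_null_mean: np.ndarray
    ratio: np.ndarray
    n_draws: int
    draw_size: int
    seed: int

    def top_pair(self) -> tuple[int, int]:
        """Position pair with the largest epistasis ratio."""
        r = np.where(np.isnan(self.ratio), -np.inf, self.ratio)
        i, j = divmod(int(np.argmax(r)), r.shape[1])
        return (i, j) if i < j else (j, i)


def epistasis_analysis(
    high_seqs,
    pool_seqs,
    n_draws: int = 1000,
    draw_size: int | None = None,
    seed: int = 0,
    replace: bool = False,
) -> EpistasisResult:
    """Observed MI on the high-productive set vs a full-library null.

    ``draw_size`` defaults to the size of the observed set, matching the
    "same number of sequences" resampling scheme.
    """
    high_m = encode_sequences(high_seqs)
    pool_m = encode_sequences(pool_seqs)
    if draw_size is None:
        draw_size = high_m.shape[0]
    observed = mi_matrix(high_m)
    null = mi_null(pool_m, n_draws=n_draws, draw_size=draw_size, seed=seed,
                   replace=replace)
    return EpistasisResult(
        mi_observed=observed,
        mi_null_mean=null,
        ratio=epistasis_ratio(observed, null),
        n_draws=n_draws,
        draw_size=draw_size,
        seed=seed,
    )
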