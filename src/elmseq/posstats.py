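"""Positional and motif-level contrasts between high- and low-productive sets.

Covers the per-position log2 odds ratio of base frequencies, DAMRatio
comparisons between motif-defined subgroups (e.g. extended -10 TGN
variants), scanning for alternative Pribnow boxes, alternative start
codons in 5'-UTRs, and a simple Shine-Dalgarno-like detector.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bonferroni

BASES = "ACGT"

ALT_PRIBNOW = ("TATAAT", "TAAAAT", "TACAAT", "TAGAAT")


def position_base_odds(
    high_seqs: Sequence[str],
    low_seqs: Sequence[str],
    alpha: float = 0.5,
    positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per (position, base) log2 odds ratio of high vs low base frequency.

    The odds ratio cancels library composition bias shared by both classes.
    Cells use the Haldane-Anscombe pseudocount ``alpha``; Fisher exact
    p-values are Bonferroni-corrected over all 4 x L cells.
    """
    if not high_seqs or not low_seqs:
        raise ValueError("both sequence sets must be non-empty")
    lengths = {len(s) for s in high_seqs} | {len(s) for s in low_seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
    L = lengths.pop()
    if positions is None:
        positions = list(range(L))
    elif len(positions) != L:
        raise ValueError("positions must label every column")

    hi = _base_count_matrix(high_seqs, L)
    lo = _base_count_matrix(low_seqs, L)
    n_hi, n_lo = len(high_seqs), len(low_seqs)

    rows = []
    for p in range(L):
        for b, base in enumerate(BASES):
            c_hi, c_lo = hi[p, b], lo[p, b]
            odds = np.log2(
                ((c_hi + alpha) / (n_hi - c_hi + alpha))
                / ((c_lo + alpha) / (n_lo - c_lo + alpha))
            )
            _, p_val = stats.fisher_exact(
                [[c_hi, n_hi - c_hi], [c_lo, n_lo - c_lo]]
            )
            rows.append(
                {
                    "position": positions[p],
                    "base": base,
                    "log2_odds": odds,
                    "count_high": int(c_hi),
                    "count_low": int(c_lo),
                    "p_value": p_val,
                }
            )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = bonferroni(df["p_value"], len(df))
    df.attrs["n_high"] = n_hi
    df.attrs["n_low"] = n_lo
    df.attrs["alpha"] = alpha
    return df


def _base_count_matrix(seqs: Sequence[str], L: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(-1, L)
    out = np.zeros((L, 4), dtype=np.int64)
    for b, base in enumerate(BASES):
        out[:, b] = (arr == ord(base)).sum(axis=0)
    return out


def motif_group_compare(
    seqs: Sequence[str],
    ratios: Sequence[float],
    motif_variants: Sequence[tuple[str, int]],
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare log10 DAMRatios between groups defined by anchored motifs.

    ``motif_variants`` is a list of (pattern, anchor offset) pairs; each
    sequence joins the group of the first variant it matches (non-matching
    sequences are excluded). Returns per-group summaries and all pairwise
    two-tailed t-tests with Bonferroni correction.
    """
    ratios = np.asarray(ratios, dtype=float)
    groups: dict[str, list[float]] = {}
    for pattern, off in motif_variants:
        key = f"{pattern}@{off}"
        groups[key] = []
    for seq, y in zip(seqs, ratios):
        for pattern, off in motif_variants:
            if off + len(pattern) > len(seq):
                raise ValueError(f"motif {pattern} at {off} exceeds sequence span")
            if seq[off:off + len(pattern)] == pattern:
                groups[f"{pattern}@{off}"].append(y)
                break

    summary = pd.DataFrame(
        [
            {
                "group": key,
                "n": len(vals),
                "mean": float(np.mean(vals)) if vals else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
            for key, vals in groups.items()
        ]
    )

    rows = []
    pairs = list(combinations(groups, 2))
    for g1, g2 in pairs:
        a, b = groups[g1], groups[g2]
        if len(a) < 2 or len(b) < 2:
            continue  # skipped comparison: group too small
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "mean_diff": float(np.mean(a) - np.mean(b)),
                "t": float(t),
                "p_value": float(p),
            }
        )
    tests = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "t", "p_value"]
    )
    if len(tests):
        tests["p_bonferroni"] = bonferroni(tests["p_value"], len(pairs))
    return summary, tests


def scan_alternative_pribnow(
    seq: str,
    motifs: Iterable[str] = ALT_PRIBNOW,
    exclude: tuple[int, int] | None = None,
    offset_coords: Sequence[int] | None = None,
) -> list[tuple[str, int]]:
    """All exact occurrences of Pribnow-box variants in a sequence.

    ``exclude`` masks a half-open index range (the fixed TATAAT position).
    Matches are reported left to right; ``offset_coords`` maps string
    indices to screen coordinates when provided.
    """
    hits = []
    for start in range(len(seq)):
        for motif in motifs:
            if exclude and exclude[0] <= start < exclude[1]:
                continue
            if seq.startswith(motif, start):
                coord = offset_coords[start] if offset_coords else start
                hits.append((motif, coord))
    return hits


def detect_alt_start_codons(
    utr_seq: str, codons: Iterable[str] = ("ATG",)
) -> list[tuple[int, int, bool]]:
    """Alternative start codons inside a 5'-UTR.

    The UTR is given 5'->3' ending immediately before the native ATG at +1.
    Returns (position coordinate of the codon's first base, distance in nt
    to the native A, in-frame flag) for every occurrence.
    """
    L = len(utr_seq)
    out = []
    for i in range(L - 2):
        codon = utr_seq[i:i + 3]
        if codon in set(codons):
            distance = L - i
            out.append((-(L - i), distance, distance % 3 == 0))
    return out


def sd_score(
    utr_seq: str,
    sd_consensus: str = "AGGAGG",
    region: tuple[int, int] = (-20, -1),
    min_run: int = 4,
) -> tuple[bool, int, int | None]:
    """Longest Shine-Dalgarno-like run in a UTR window.

    Finds the longest contiguous stretch of the UTR region that matches the
    SD consensus (equivalently, that base-pairs contiguously and
    antiparallel with the 16S rRNA anti-SD, the consensus' reverse
    complement). Returns (has_sd, best run length, start index in the UTR or
    None). This rule is a declared approximation: the assay species'
    anti-SD is configurable, not asserted.
    """
    L = len(utr_seq)
    lo = max(0, L + region[0])
    hi = L + region[1] + 1
    window = utr_seq[lo:hi]
    best, best_pos = 0, None
    for i in range(len(window)):
        for j in range(len(sd_consensus)):
            run = 0
            while (
                i + run < len(window)
                and j + run < len(sd_consensus)
                and window[i + run] == sd_consensus[j + run]
            ):
                run += 1
            if run > best:
                best, best_pos = run, lo + i
    return best >= min_run, best, best_pos
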