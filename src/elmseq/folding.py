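"""RNA folding energies behind a pluggable provider, window scans, exposure.

Translation efficiency depends on mRNA secondary structure around the
ribosome entry region, so we scan every (start, end) folding window over
the transcript, fold the windowed subsequence, and correlate its free
energy with log10 DAMRatio across variants.

Two providers implement the ``fold`` contract:

* :class:`NussinovProvider` — a deterministic maximum-base-pairing model
  (Watson-Crick + GU wobble, minimum hairpin loop of 3, -1.0 kcal/mol per
  pair). It is a self-contained combinatorial stand-in with the right
  qualitative behavior (more pairing => lower energy), not a thermodynamic
  nearest-neighbor model.
* :class:`ViennaProvider` — minimum free energy and structure from an
  installed ``RNAfold`` binary, when present.

Window coordinates follow the UTR convention: -26 is the transcript 5' end
of a 26-nt UTR, +1 the A of the start codon, and there is no position 0.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd

_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
# Allowed pairs on codes: AU, UA, CG, GC, GU, UG
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for a, b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[a, b] = True

MIN_LOOP = 3


def transcribe(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _encode_rna(seqs: list[str]) -> np.ndarray:
    L = len(seqs[0])
    out = np.empty((len(seqs), L), dtype=np.int8)
    for r, s in enumerate(seqs):
        for c, ch in enumerate(s):
            out[r, c] = _RNA_CODE[ch]
    return out


def _max_pairs_batch(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum base pairs for a batch of equal-length sequences.

    Returns (pair counts per sequence, full DP table) — the table is kept
    for traceback. DP over spans with the bifurcation max vectorized over
    the batch.
    """
    B, n = codes.shape
    M = np.zeros((B, n + 1, n + 1), dtype=np.int16)  # M[:, i, j] over [i, j)
    can = _PAIRABLE[codes[:, :, None], codes[:, None, :]]  # (B, n, n)
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(n - span + 1):
            j = i + span  # window [i, j)
            # bifurcation: max_k M[i,k) + M[k,j), k in (i, j)
            left = M[:, i, i + 1:j]
            right = M[:, i + 1:j, j]
            best = (left + right).max(axis=1)
            # pair the two ends i and j-1
            paired = M[:, i + 1, j - 1] + can[:, i, j - 1]
            M[:, i, j] = np.maximum(best, paired)
    return M[:, 0, n].astype(np.int64), M


def _traceback(codes_row: np.ndarray, M: np.ndarray) -> str:
    """Dot-bracket structure for one sequence from its DP table."""
    n = codes_row.shape[0]
    struct = ["."] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 2:
            continue
        target = M[i, j]
        if target == 0:
            continue
        if (
            _PAIRABLE[codes_row[i], codes_row[j - 1]]
            and M[i + 1, j - 1] + 1 == target
        ):
            struct[i], struct[j - 1] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if M[i, k] + M[k, j] == target:
                stack.append((i, k))
                stack.append((k, j))
                break
    return "".join(struct)


class NussinovProvider:
    """Deterministic maximum-pairing folding stub (-1 kcal/mol per pair)."""

    name = "stub"
    energy_per_pair = -1.0

    def fold(self, seq: str) -> tuple[float, str]:
        rna = transcribe(seq)
        if not rna:
            raise ValueError("empty sequence")
        codes = _encode_rna([rna])
        pairs, M = _max_pairs_batch(codes)
        structure = _traceback(codes[0], M[0])
        return self.energy_per_pair * float(pairs[0]), structure

    def fold_many(self, seqs: list[str]) -> np.ndarray:
        """Energies for a batch of equal-length sequences (no structures)."""
        rnas = [transcribe(s) for s in seqs]
        codes = _encode_rna(rnas)
        pairs, _ = _max_pairs_batch(codes)
        return self.energy_per_pair * pairs.astype(float)


class ViennaProvider:
    """Minimum free energy via an external RNAfold executable."""

    name = "vienna"

    def __init__(self, binary: str = "RNAfold"):
        if shutil.which(binary) is None:
            raise RuntimeError(
                f"folding backend unavailable: {binary!r} not on PATH; "
                "use the stub provider or install ViennaRNA"
            )
        self.binary = binary

    def fold(self, seq: str) -> tuple[float, str]:
        rna = transcribe(seq)
        out = subprocess.run(
            [self.binary, "--noPS"],
            input=rna + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout.splitlines()
        structure, energy = out[1].rsplit(" ", 1)
        return float(energy.strip("() ")), structure.strip()

    def fold_many(self, seqs: list[str]) -> np.ndarray:
        return np.array([self.fold(s)[0] for s in seqs])


def get_provider(name: str = "stub"):
    if name == "stub":
        return NussinovProvider()
    if name == "vienna":
        return ViennaProvider()
    raise ValueError(f"unknown folding provider {name!r}")


def fold_energy(seq: str, provider=None) -> float:
    """Folding free energy (kcal/mol) of one sequence."""
    provider = provider or NussinovProvider()
    return provider.fold(seq)[0]


@dataclass
class FoldScan:
    """Window-scan result: per-window Pearson r between dG and expression."""

    table: pd.DataFrame  # columns: start, end, r, n
    best_start: int
    best_end: int
    best_r: float


def window_scan(
    mrnas: list[str],
    ratios,
    start_range: tuple[int, int] = (-26, -1),
    end_range: tuple[int, int] = (-10, 100),
    provider=None,
    utr_length: int = 26,
    min_window: int = 8,
) -> FoldScan:
    """Correlate windowed folding energy with log10 DAMRatio per window.

    For every admissible (start, end) coordinate pair the window's folding
    energy is computed for all transcripts and correlated with the
    expression measure; windows extending beyond the available sequence or
    shorter than ``min_window`` are reported as NaN. The strongest-|r|
    window is recorded.
    """
    provider = provider or NussinovProvider()
    y = np.asarray(ratios, dtype=float)
    if len(mrnas) != len(y):
        raise ValueError("one expression value per transcript required")
    if len(y) < 3:
        raise ValueError("correlation needs at least 3 variants")
    seq_len = min(len(m) for m in mrnas)

    def to_index(coord: int) -> int:
        if coord == 0:
            raise ValueError("position 0 does not exist")
        return utr_length + coord if coord < 0 else utr_length + coord - 1

    rows = []
    for start in _coord_range(*start_range):
        i0 = to_index(start)
        for end in _coord_range(*end_range):
            i1 = to_index(end) + 1
            if i1 <= i0:
                continue
            if i0 < 0 or i1 > seq_len or (i1 - i0) < min_window:
                rows.append({"start": start, "end": end, "r": np.nan, "n": 0})
                continue
            dg = provider.fold_many([m[i0:i1] for m in mrnas])
            r = np.nan if np.std(dg) == 0 else float(np.corrcoef(dg, y)[0, 1])
            rows.append({"start": start, "end": end, "r": r, "n": len(y)})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["r"])
    if len(valid):
        best = valid.loc[valid["r"].abs().idxmax()]
        return FoldScan(table, int(best["start"]), int(best["end"]), float(best["r"]))
    return FoldScan(table, 0, 0, np.nan)


def _coord_range(lo: int, hi: int):
    return [c for c in range(lo, hi + 1) if c != 0]


def exposure_profile(seq: str, structure: str) -> np.ndarray:
    """Boolean exposed/hidden profile: a position is hidden iff paired."""
    if len(seq) != len(structure):
        raise ValueError("structure length must match sequence length")
    depth = 0
    exposed = np.empty(len(structure), dtype=bool)
    for k, ch in enumerate(structure):
        if ch == "(":
            depth += 1
            exposed[k] = False
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket structure")
            exposed[k] = False
        elif ch == ".":
            exposed[k] = True
        else:
            raise ValueError(f"invalid structure character {ch!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket structure")
    return exposed


def exposure_compare(
    high: tuple[np.ndarray, list[str]],
    low: tuple[np.ndarray, list[str]],
    bin_width: float = 1.0,
    positions=None,
) -> pd.DataFrame:
    """Per-position exposure enrichment of high- vs low-productive sets.

    Both sets carry (dG array, dot-bracket structures) for one fixed
    folding region. Sequences are stratified into dG bins of ``bin_width``
    kcal/mol so that overall folding stability is controlled; within each
    bin the per-position exposed fraction is compared, and bins are
    combined into a size-weighted log2 enrichment. Fisher exact p-values
    (on pooled exposed/hidden counts) are Bonferroni-corrected.
    """
    from scipy.stats import fisher_exact

    dg_hi, struct_hi = np.asarray(high[0], float), high[1]
    dg_lo, struct_lo = np.asarray(low[0], float), low[1]
    exp_hi = np.stack([exposure_profile("N" * len(s), s) for s in struct_hi])
    exp_lo = np.stack([exposure_profile("N" * len(s), s) for s in struct_lo])
    L = exp_hi.shape[1]
    if positions is None:
        positions = list(range(L))

    all_dg = np.concatenate([dg_hi, dg_lo])
    edges = np.arange(all_dg.min(), all_dg.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([all_dg.min(), all_dg.min() + bin_width])
    bins_hi = np.clip(np.digitize(dg_hi, edges) - 1, 0, len(edges) - 2)
    bins_lo = np.clip(np.digitize(dg_lo, edges) - 1, 0, len(edges) - 2)

    enrich = np.zeros(L)
    weight_total = 0.0
    for b in range(len(edges) - 1):
        m_hi, m_lo = bins_hi == b, bins_lo == b
        if not m_hi.any() or not m_lo.any():
            continue  # empty bin skipped
        w = m_hi.sum() + m_lo.sum()
        f_hi = (exp_hi[m_hi].sum(axis=0) + 0.5) / (m_hi.sum() + 1.0)
        f_lo = (exp_lo[m_lo].sum(axis=0) + 0.5) / (m_lo.sum() + 1.0)
        enrich += w * np.log2(f_hi / f_lo)
        weight_total += w
    enrich = enrich / weight_total if weight_total else np.full(L, np.nan)

    p_vals = []
    for k in range(L):
        table = [
            [int(exp_hi[:, k].sum()), int((~exp_hi[:, k]).sum())],
            [int(exp_lo[:, k].sum()), int((~exp_lo[:, k]).sum())],
        ]
        p_vals.append(fisher_exact(table)[1])
    out = pd.DataFrame(
        {
            "position": positions,
            "log2_exposure_enrichment": enrich,
            "exposed_frac_high": exp_hi.mean(axis=0),
            "exposed_frac_low": exp_lo.mean(axis=0),
            "p_value": p_vals,
        }
    )
    out["p_bonferroni"] = np.minimum(out["p_value"] * L, 1.0)
    return out
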