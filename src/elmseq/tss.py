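"""Gene-specific RNA-seq: 5'-UTR length mapping, TPM, TSS calls.

Reads from the dam-specific RNA-seq protocol capture the 5' end of each
transcript: a short ligation barcode, then however much of the 26-nt
5'-UTR the transcript carries, then the dam coding sequence. Filtering
keeps reads containing the dam 5' anchor; the UTR portion is matched as an
exact suffix of a known library variant's UTR, giving a (variant, UTR
length) assignment. The most frequent length per variant is its called
TSS: a 26-nt UTR is the theoretical +1 start ("N7", 7 nt after the Pribnow
box), 25 nt is "N8", and so on.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .templates import RNA_DAM_ANCHOR

FULL_UTR_LENGTH = 26
_AMBIGUOUS = object()


def filter_rna_reads(
    reads: Iterable[str], anchor: str = RNA_DAM_ANCHOR
) -> tuple[list[str], dict]:
    """Keep reads containing the dam-coding anchor exactly."""
    kept, discarded = [], 0
    for read in reads:
        if anchor in read:
            kept.append(read)
        else:
            discarded += 1
    return kept, {"kept": len(kept), "discarded": discarded}


def build_suffix_index(
    library: Mapping[str, str], min_len: int = 15
) -> dict[str, object]:
    """Map every admissible UTR suffix to its variant (or ambiguous marker).

    ``library`` maps variant id -> full UTR sequence (fixed transcript +1
    base followed by the 25 randomized nt).
    """
    index: dict[str, object] = {}
    for variant, utr in library.items():
        for l in range(min_len, len(utr) + 1):
            suffix = utr[-l:]
            existing = index.get(suffix)
            if existing is None:
                index[suffix] = variant
            elif existing is not _AMBIGUOUS and existing != variant:
                index[suffix] = _AMBIGUOUS
    return index


def map_utr_lengths(
    reads: Iterable[str],
    library: Mapping[str, str],
    min_len: int = 15,
    barcode_length: int = 6,
    anchor: str = RNA_DAM_ANCHOR,
) -> tuple[dict[str, Counter], dict]:
    """Assign each read to a (variant, UTR length) by exact suffix match.

    The leading ``barcode_length`` bases are trimmed, the UTR portion is
    everything before the dam anchor, and it must equal the 3'-most l bases
    of exactly one library UTR with l >= ``min_len``. A full-length (26 nt)
    match requires the correct promoter +1 base because that base is part
    of the stored UTR. Ambiguous and unmatched reads are discarded with a
    tally.
    """
    index = build_suffix_index(library, min_len=min_len)
    counts: dict[str, Counter] = defaultdict(Counter)
    tally = {"mapped": 0, "too_short": 0, "ambiguous": 0, "unmapped": 0,
             "no_anchor": 0}
    for read in reads:
        body = read[barcode_length:]
        cut = body.find(anchor)
        if cut < 0:
            tally["no_anchor"] += 1
            continue
        utr_portion = body[:cut]
        l = len(utr_portion)
        if l < min_len:
            tally["too_short"] += 1
            continue
        hit = index.get(utr_portion)
        if hit is None:
            tally["unmapped"] += 1
        elif hit is _AMBIGUOUS:
            tally["ambiguous"] += 1
        else:
            counts[hit][l] += 1
            tally["mapped"] += 1
    return dict(counts), tally


def tpm(n_il, n_tot: int):
    """Transcripts per million: N_il / N_tot * 1e6 (no pseudocount)."""
    if n_tot <= 0:
        raise ValueError("total filtered read count must be positive")
    return np.asarray(n_il, dtype=float) / n_tot * 1e6


def call_tss(length_counts: Mapping[int, int]) -> tuple[int, str, bool]:
    """TSS = the UTR length with the most reads; ties go to the longer UTR.

    Returns (called length, N-style label, tie flag). Length 26 is the
    theoretical +1 ("N7"); each base shorter starts one position later.
    """
    if not length_counts:
        raise ValueError("no retained UTR lengths for this variant")
    best = max(length_counts.values())
    winners = [l for l, c in length_counts.items() if c == best]
    called = max(winners)
    label = f"N{7 + (FULL_UTR_LENGTH - called)}"
    return called, label, len(winners) > 1


def normalize_by_dna(rna_abundance: float, uncut_count: float) -> tuple[float, bool]:
    """Divide RNA abundance by log10 of the uncut-pool DNA read count.

    Variants with uncut count <= 1 (log10 <= 0) are returned unnormalized
    with a flag.
    """
    if uncut_count <= 1:
        return float(rna_abundance), False
    return float(rna_abundance) / np.log10(uncut_count), True


def build_tss_table(
    reads: Iterable[str],
    library: Mapping[str, str],
    uncut_counts: Mapping[str, int] | None = None,
    min_len: int = 15,
    barcode_length: int = 6,
    anchor: str = RNA_DAM_ANCHOR,
) -> tuple[pd.DataFrame, dict]:
    """Full RNA-seq path: filter, map, TPM, TSS calls, DNA normalization."""
    kept, filter_stats = filter_rna_reads(reads, anchor=anchor)
    counts, map_stats = map_utr_lengths(
        kept, library, min_len=min_len, barcode_length=barcode_length,
        anchor=anchor,
    )
    n_tot = len(kept)
    rows = []
    for variant, lengths in counts.items():
        called, label, tie = call_tss(lengths)
        abundance = float(tpm(sum(lengths.values()), n_tot))
        row = {
            "variant": variant,
            "n_reads": int(sum(lengths.values())),
            "tss_utr_length": called,
            "tss_label": label,
            "tss_tie": tie,
            "rna_abundance_tpm": abundance,
        }
        if uncut_counts is not None:
            value, flagged = normalize_by_dna(
                abundance, uncut_counts.get(variant, 0)
            )
            row["dna_normalized_abundance"] = value
            row["dna_normalized"] = flagged
        rows.append(row)
    df = pd.DataFrame(rows).set_index("variant") if rows else pd.DataFrame()
    stats = {"filter": filter_stats, "mapping": map_stats, "n_tot": n_tot}
    return df, stats
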