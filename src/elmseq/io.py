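"""Reading and writing of sequence files and tab-separated tables."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_seqs(path) -> Iterator[str]:
    """Yield sequences from FASTQ or FASTA (plain or gzipped)."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield str(rec.seq).upper()


def write_fastq(path, seqs: Iterable[str], prefix: str = "read") -> int:
    """Write sequences as FASTQ with uniform quality; returns read count."""
    n = 0
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_table(df: pd.DataFrame, path, index_label: str | None = "variant") -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_table(path, index_col: str | None = "variant") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
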