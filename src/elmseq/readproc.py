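"""From raw amplicon reads to per-variant, per-condition count tables.

Reads are demultiplexed into the three digestion conditions (uncut, DpnI,
MboI), filtered by exact matches to the constant construct anchors, and the
randomized bases are extracted in sense orientation and tabulated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .templates import ConstructTemplate, revcomp

CONDITIONS = ("uncut", "dpn", "mbo")


@dataclass
class CountTable:
    """Per-variant accepted-read counts for the three digestion pools.

    ``counts`` is a DataFrame indexed by variant with integer columns
    uncut/dpn/mbo; totals are accepted reads only — rejected reads are
    tracked separately in ``rejected`` by condition and reason.
    """

    counts: pd.DataFrame
    rejected: dict = field(default_factory=dict)

    @property
    def totals(self) -> dict:
        return {c: int(self.counts[c].sum()) for c in CONDITIONS}

    def __len__(self) -> int:
        return len(self.counts)


def demultiplex(
    reads: Iterable[tuple[str, str]], index_map: dict[str, str]
) -> tuple[dict[str, list[str]], Counter]:
    """Assign (index, sequence) reads to conditions by exact index lookup.

    Returns per-condition sequence lists and a tally of rejected reads
    (reason ``unknown_index``).
    """
    if len(set(index_map.values())) != len(index_map):
        # several indexes may map to one condition, but warn-level situations
        # (duplicate keys) cannot occur in a dict; nothing to check here.
        pass
    pools: dict[str, list[str]] = {c: [] for c in dict.fromkeys(index_map.values())}
    tally: Counter = Counter()
    for index, seq in reads:
        cond = index_map.get(index)
        if cond is None:
            tally["unknown_index"] += 1
        else:
            pools[cond].append(seq)
            tally[f"assigned_{cond}"] += 1
    return pools, tally


def extract_variant(
    read: str, template: ConstructTemplate, floating: bool = False
) -> tuple[str | None, str | None]:
    """Extract the randomized bases from one raw read.

    Returns ``(variant, None)`` on success or ``(None, reason)`` on
    rejection. All constant segments must match exactly; the variant is
    returned in sense orientation regardless of read orientation.
    """
    read = read.upper()
    sense = revcomp(read) if template.orientation == "reverse" else read
    if floating:
        return _extract_floating(sense, template)
    if len(sense) < template.span:
        return None, "too_short"
    parts = []
    for k, (seg, off) in enumerate(template.segment_offsets()):
        chunk = sense[off:off + seg.length]
        if seg.kind == "const":
            if chunk != seg.value:
                return None, f"anchor_mismatch_{k}"
        else:
            if "N" in chunk:
                return None, "ambiguous_base"
            parts.append(chunk)
    return "".join(parts), None


def _extract_floating(sense: str, template: ConstructTemplate):
    """Locate anchors by search instead of fixed offsets (robustness mode)."""
    pos, parts, pending_n = 0, [], 0
    for k, seg in enumerate(template.segments):
        if seg.kind == "N":
            pending_n += seg.length
            continue
        hit = sense.find(seg.value, pos)
        if hit < 0:
            return None, f"anchor_mismatch_{k}"
        if pending_n:
            chunk = sense[hit - pending_n:hit]
            if hit - pending_n < pos or len(chunk) != pending_n:
                return None, "length_mismatch"
            if "N" in chunk:
                return None, "ambiguous_base"
            parts.append(chunk)
            pending_n = 0
        pos = hit + seg.length
    if pending_n:  # trailing N-run
        chunk = sense[pos:pos + pending_n]
        if len(chunk) != pending_n:
            return None, "too_short"
        if "N" in chunk:
            return None, "ambiguous_base"
        parts.append(chunk)
    return "".join(parts), None


def extract_pool(
    reads: Iterable[str], template: ConstructTemplate, floating: bool = False
) -> tuple[list[str], Counter]:
    """extract_variant over a read pool; returns variants + rejection tally."""
    variants, tally = [], Counter()
    for read in reads:
        variant, reason = extract_variant(read, template, floating=floating)
        if variant is None:
            tally[reason] += 1
        else:
            variants.append(variant)
            tally["accepted"] += 1
    return variants, tally


def tabulate(labeled_variants: dict[str, Iterable[str]]) -> CountTable:
    """Exact multiset counts per condition for accepted variants."""
    counters = {c: Counter(labeled_variants.get(c, ())) for c in CONDITIONS}
    all_variants = sorted(set().union(*[c.keys() for c in counters.values()]))
    lengths = {len(v) for v in all_variants}
    if len(lengths) > 1:
        raise ValueError(f"mixed variant lengths in one screen: {sorted(lengths)}")
    df = pd.DataFrame(
        {c: [counters[c][v] for v in all_variants] for c in CONDITIONS},
        index=pd.Index(all_variants, name="variant"),
        dtype=int,
    )
    return CountTable(counts=df)


def count_pools(
    template: ConstructTemplate,
    uncut: Iterable[str],
    dpn: Iterable[str],
    mbo: Iterable[str],
    floating: bool = False,
) -> CountTable:
    """Full read-processing path: anchor-filter three pools and tabulate."""
    pools, rejected = {}, {}
    for cond, reads in zip(CONDITIONS, (uncut, dpn, mbo)):
        variants, tally = extract_pool(reads, template, floating=floating)
        pools[cond] = variants
        rejected[cond] = dict(tally)
    table = tabulate(pools)
    table.rejected = rejected
    return table
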