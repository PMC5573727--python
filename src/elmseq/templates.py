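"""Construct templates for the three reporter screens.

Each screen inserts a randomized region into a fixed Dam-reporter cassette.
Raw sequencing reads come off the machine as reverse complements of the
construct sense strand, so the anchors used for read filtering are stored
here in both orientations.

Coordinate conventions (no position 0 anywhere):

* promoter screen: positions -37..-13 are the 25 randomized bases upstream
  of the fixed Pribnow box (TATAAT, -12..-7); -6..+1 are the 7 randomized
  bases downstream, with +1 the theoretical transcription start.
* 5'-UTR screens: the 25 randomized bases sit at -25..-1 upstream of the
  +1 = A of the dam ATG; position -26 is the fixed transcript first base
  (the promoter +1: T for the strong promoter, A for the weak one).
"""

from __future__ import annotations

from dataclasses import dataclass, field


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


# Filtering anchors in raw-read (reverse complement) orientation.
DAM_CDS_RC = "TGCCCACTTCAAAAAAGCGCGATTTTTCTTCAT"
PROMOTER_CASSETTE_RC = "GACCGGAACTTCTATGATCGAGATCGAGATCGAGATCGCGGCCGCAAC"
UTR_STRONG_PROMOTER_RC = "AGTTTATATTATAACACTTTAACCTATGGC"
UTR_WEAK_PROMOTER_RC = "TGCAATTATTCTAACAAACCCCAAACTTATTTCAA"

# Same anchors on the construct sense strand.
DAM_CDS = revcomp(DAM_CDS_RC)                    # starts ATGAAGAAAAATCG...
PROMOTER_CASSETTE = revcomp(PROMOTER_CASSETTE_RC)
UTR_STRONG_PROMOTER = revcomp(UTR_STRONG_PROMOTER_RC)   # ends in the +1 'T'
UTR_WEAK_PROMOTER = revcomp(UTR_WEAK_PROMOTER_RC)       # ends in the +1 'A'

# 5'-end anchor of dam mRNA reads in the gene-specific RNA-seq protocol.
RNA_DAM_ANCHOR = "ATGAAGAAAAATCG"

PRIBNOW = "TATAAT"

# Dam coding context used for mRNA folding windows. Only the first 33 nt of
# the dam reading frame are fixed by the cassette anchors above; the
# remainder is a synthetic, arbitrary in-frame continuation (no stop codon in
# the first 100 nt) so that folding windows extending up to +100 always have
# sequence under them. It is NOT the M. pneumoniae dam gene sequence.
_SYNTHETIC_CODING_TAIL = (
    "GCTAAAGTTGACCGTATTGAACTGGCTCGTAAAGGTATCGACCTGAAACATCCGGAAGTTCTG"
    "GCTCGTATCAAAGAAGCTCTGGGTAAAGACCTG"
)
DAM_CODING_CONTEXT = DAM_CDS + _SYNTHETIC_CODING_TAIL


@dataclass(frozen=True)
class Segment:
    """One piece of a construct layout: a constant string or an N-run."""

    kind: str          # "const" | "N"
    value: str = ""    # constant sequence (kind == "const")
    length: int = 0    # N-run length (kind == "N")

    def __post_init__(self):
        if self.kind == "const":
            object.__setattr__(self, "length", len(self.value))
        elif self.kind != "N":
            raise ValueError(f"unknown segment kind {self.kind!r}")


def const(seq: str) -> Segment:
    return Segment("const", value=seq)


def nrun(length: int) -> Segment:
    return Segment("N", length=length)


@dataclass(frozen=True)
class ConstructTemplate:
    """Layout of one screen's construct on the sense strand.

    ``orientation == "reverse"`` means raw reads are reverse complements of
    the sense strand and are flipped before anchor matching.
    """

    screen_id: str
    segments: tuple[Segment, ...]
    orientation: str = "reverse"
    variant_positions: tuple[int, ...] = ()
    plus_one_base: str = ""      # UTR screens: fixed transcript first base
    coding_context: str = ""     # downstream coding sequence for folding
    barcode_length: int = 6      # RNA-seq 5' barcode bases to trim

    def __post_init__(self):
        for seg in self.segments:
            if seg.kind == "const":
                if len(seg.value) >= 10 and (set(seg.value) - set("ACGT")):
                    raise ValueError(f"anchor contains non-ACGT: {seg.value}")
        if self.variant_positions and len(self.variant_positions) != self.variant_length:
            raise ValueError(
                f"{len(self.variant_positions)} coordinates for "
                f"{self.variant_length} randomized bases"
            )

    @property
    def span(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def variant_length(self) -> int:
        return sum(s.length for s in self.segments if s.kind == "N")

    def segment_offsets(self) -> list[tuple[Segment, int]]:
        out, pos = [], 0
        for seg in self.segments:
            out.append((seg, pos))
            pos += seg.length
        return out

    def fill(self, variant: str) -> str:
        """Sense-strand sequence of the construct carrying ``variant``."""
        if len(variant) != self.variant_length:
            raise ValueError(
                f"variant length {len(variant)} != {self.variant_length}"
            )
        parts, used = [], 0
        for seg in self.segments:
            if seg.kind == "const":
                parts.append(seg.value)
            else:
                parts.append(variant[used:used + seg.length])
                used += seg.length
        return "".join(parts)

    def raw_read(self, variant: str) -> str:
        """The read the sequencer would report for ``variant`` (no errors)."""
        sense = self.fill(variant)
        return revcomp(sense) if self.orientation == "reverse" else sense

    def full_utr(self, variant: str) -> str:
        """26-nt 5'-UTR (fixed +1 base + 25 randomized nt); UTR screens only."""
        if not self.plus_one_base:
            raise ValueError(f"screen {self.screen_id} has no 5'-UTR layout")
        return self.plus_one_base + variant

    def mrna(self, variant: str) -> str:
        """Transcript from the theoretical TSS: full UTR + coding context."""
        return self.full_utr(variant) + self.coding_context

    def coord_to_index(self, coord: int, utr_length: int = 26) -> int:
        """Map a UTR-style coordinate (-utr_length..-1, +1..) to an mRNA index."""
        if coord == 0:
            raise ValueError("position 0 does not exist")
        return utr_length + coord if coord < 0 else utr_length + coord - 1


def _promoter_positions() -> tuple[int, ...]:
    # N25 at -37..-13, N7 at -6..+1 (0 skipped).
    return tuple(range(-37, -12)) + tuple(range(-6, 0)) + (1,)


def promoter_template() -> ConstructTemplate:
    return ConstructTemplate(
        screen_id="promoter",
        segments=(
            const(PROMOTER_CASSETTE),
            nrun(25),
            const(PRIBNOW),
            nrun(7),
            const(DAM_CDS),
        ),
        variant_positions=_promoter_positions(),
    )


def utr_template(promoter: str) -> ConstructTemplate:
    if promoter == "strong":
        anchor, plus_one = UTR_STRONG_PROMOTER, "T"
    elif promoter == "weak":
        anchor, plus_one = UTR_WEAK_PROMOTER, "A"
    else:
        raise ValueError("promoter must be 'strong' or 'weak'")
    return ConstructTemplate(
        screen_id=f"utr_{promoter}",
        segments=(const(anchor), nrun(25), const(DAM_CDS)),
        variant_positions=tuple(range(-25, 0)),
        plus_one_base=plus_one,
        coding_context=DAM_CODING_CONTEXT,
    )


def get_template(screen_id: str) -> ConstructTemplate:
    if screen_id == "promoter":
        return promoter_template()
    if screen_id == "utr_strong":
        return utr_template("strong")
    if screen_id == "utr_weak":
        return utr_template("weak")
    raise ValueError(f"unknown screen {screen_id!r}")
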