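"""Sequence-motif annotation around transcript ends and splice junctions.

Three scans, all strand-aware and all on genomic coordinates:

* polyadenylation: the canonical AATAAA hexamer within 20 bp of a read's
  aligned 3' end (variant hexamers such as ATTAAA only behind an explicit
  flag);
* splice junctions: the intronic dinucleotides flanking each inter-block
  gap, flagged canonical when they follow the GT donor / AG acceptor rule;
* Kozak contexts: every ATG whose 7-mer context (positions -3..+4) fits
  A-N-N-A-T-G-G on a transcript's sense strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .align import reverse_complement
from .classify import ReadBlocks
from .errors import InputError

__all__ = [
    "PolyASite",
    "JunctionCall",
    "KozakSite",
    "find_polya",
    "validate_junctions",
    "find_kozak",
]

CANONICAL_POLYA = "AATAAA"
VARIANT_POLYA = ("ATTAAA",)


@dataclass(frozen=True)
class PolyASite:
    read_id: str
    position: int  # genomic start of the hexamer
    motif: str
    distance_from_end: int  # bp between motif end and aligned 3' end


@dataclass(frozen=True)
class JunctionCall:
    donor_position: int  # genomic start of the intron
    acceptor_position: int  # genomic end of the intron (exclusive)
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    canonical: bool


@dataclass(frozen=True)
class KozakSite:
    position: int  # transcript position of the ATG's A
    context: str  # 7-mer, positions -3..+4
    matches_pattern: bool


def _motifs(include_variants: bool):
    return (CANONICAL_POLYA,) + (VARIANT_POLYA if include_variants else ())


def find_polya(
    read_id: str,
    alignment_end: int,
    genome: str,
    strand: str = "+",
    window: int = 20,
    *,
    include_variants: bool = False,
) -> PolyASite | None:
    """Scan the ``window`` bp of genome ending at the aligned 3' end for a
    polyadenylation hexamer on the transcribed strand.

    ``alignment_end`` is the 3'-most aligned coordinate, exclusive: the
    block end for plus-strand reads, the block start for minus-strand
    reads. The motif must lie fully inside the window; the occurrence
    closest to the end wins. Windows truncated by a sequence edge are
    scanned as far as possible, with a warning.
    """
    if not 0 <= alignment_end <= len(genome):
        raise InputError("alignment end outside genome bounds")
    if strand == "+":
        lo = alignment_end - window
        if lo < 0:
            warnings.warn("polyA window truncated at sequence start")
            lo = 0
        segment = genome[lo:alignment_end]
    else:
        hi = alignment_end + window
        if hi > len(genome):
            warnings.warn("polyA window truncated at sequence end")
            hi = len(genome)
        segment = reverse_complement(genome[alignment_end:hi])
    best = None
    for motif in _motifs(include_variants):
        i = segment.rfind(motif)
        if i < 0:
            continue
        dist = len(segment) - (i + len(motif))
        if best is None or dist < best[0]:
            best = (dist, i, motif)
    if best is None:
        return None
    dist, i, motif = best
    if strand == "+":
        pos = max(0, alignment_end - window) + i
    else:
        pos = alignment_end + dist  # genomic start of the (reverse) hexamer
    return PolyASite(read_id, pos, motif, dist)


def validate_junctions(blocks: ReadBlocks, genome: str) -> list[JunctionCall]:
    """Report donor/acceptor dinucleotides for every inter-block gap.

    Dinucleotides are read on the transcribed strand: a canonical intron
    shows GT at its 5' (donor) end and AG at its 3' (acceptor) end.
    Gaps shorter than 4 bp cannot hold both dinucleotides and are skipped
    with a warning. Single-block reads yield an empty list.
    """
    calls = []
    for (_, e1), (s2, _) in zip(blocks.blocks, blocks.blocks[1:]):
        if s2 - e1 < 4:
            warnings.warn(f"gap of {s2 - e1} bp in read {blocks.read_id}: skipped")
            continue
        left = genome[e1 : e1 + 2]
        right = genome[s2 - 2 : s2]
        if blocks.strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = reverse_complement(right), reverse_complement(left)
        calls.append(
            JunctionCall(e1, s2, donor, acceptor, donor == "GT" and acceptor == "AG")
        )
    return calls


def find_kozak(transcript: str) -> list[KozakSite]:
    """All ATG codons whose -3..+4 context matches A-N-N-A-T-G-G, sorted by
    position. ATGs within 3 nt of the start (or lacking a +4 base) have an
    undefined context and are skipped."""
    sites = []
    i = transcript.find("ATG", 3)
    while i != -1:
        if i + 4 <= len(transcript):
            ctx = transcript[i - 3 : i + 4]
            if ctx[0] == "A" and ctx[6] == "G":
                sites.append(KozakSite(i, ctx, True))
        i = transcript.find("ATG", i + 1)
    return sites
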