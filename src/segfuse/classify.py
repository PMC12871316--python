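"""Fusion / solo transcript classification and quantification.

A read's exon blocks decide its class: overlapping exons of both the
upstream partial duplicate (gene A) and the downstream gene (gene B) makes
it a fusion; one side only makes it a solo read of that gene. Reads with a
single exon block are excluded from transcript counts altogether, and
antisense reads are left unassigned. "Spanning the merged exon boundaries"
is operationalised as dual-gene exon overlap of at least
``min_exon_overlap`` bp per side (robust to alignment jitter); an optional
strict-junction mode additionally requires the read to splice exactly at
the merged junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError, ParameterError
from .simulate import FUSION, SOLO_A, SOLO_B, FusionGeneModel

__all__ = [
    "EXCLUDED",
    "UNASSIGNED",
    "ReadBlocks",
    "ClassCounts",
    "classify_read",
    "count_classes",
    "fusion_fraction",
    "tpm_normalize",
]

EXCLUDED = "EXCLUDED"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ReadBlocks:
    read_id: str
    chrom: str
    blocks: tuple
    strand: str = "+"

    def __post_init__(self):
        if not self.blocks:
            raise InputError("a read needs at least one block")
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise InputError("blocks must be sorted and non-overlapping")


@dataclass
class ClassCounts:
    solo_a: int = 0
    solo_b: int = 0
    fusion: int = 0
    excluded_single_exon: int = 0
    unassigned: int = 0


def _overlap(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _hits(blocks, exons, min_bp: int) -> bool:
    return any(_overlap(b, e) >= min_bp for b in blocks for e in exons)


def classify_read(
    blocks: ReadBlocks,
    model: FusionGeneModel,
    min_exon_overlap: int = 10,
    *,
    strict_junction: bool = False,
) -> str:
    """Classify one read against the fused locus model.

    Order of precedence: single-exon reads are EXCLUDED before anything
    else; antisense reads are UNASSIGNED; then FUSION requires exon
    overlap on both genes (plus, in strict mode, a splice exactly at the
    merged junction), SOLO_A / SOLO_B one side only.
    """
    if blocks.chrom != model.chrom:
        raise InputError(
            f"read {blocks.read_id} on {blocks.chrom}, model on {model.chrom}"
        )
    if len(blocks.blocks) == 1:
        return EXCLUDED
    if blocks.strand != model.strand:
        return UNASSIGNED
    hit_a = _hits(blocks.blocks, model.gene_a_exons, min_exon_overlap)
    hit_b = _hits(blocks.blocks, model.gene_b_exons, min_exon_overlap)
    if hit_a and hit_b:
        if strict_junction:
            donor, acceptor = model.merged_junction
            spliced = any(
                e1 == donor and s2 == acceptor
                for (_, e1), (s2, _) in zip(blocks.blocks, blocks.blocks[1:])
            )
            return FUSION if spliced else UNASSIGNED
        return FUSION
    if hit_a:
        return SOLO_A
    if hit_b:
        return SOLO_B
    return UNASSIGNED


def count_classes(classes) -> ClassCounts:
    """Tally classified reads; accepts any iterable of class labels."""
    counts = ClassCounts()
    for c in classes:
        if c == SOLO_A:
            counts.solo_a += 1
        elif c == SOLO_B:
            counts.solo_b += 1
        elif c == FUSION:
            counts.fusion += 1
        elif c == EXCLUDED:
            counts.excluded_single_exon += 1
        elif c == UNASSIGNED:
            counts.unassigned += 1
        else:
            raise InputError(f"unknown class label {c!r}")
    return counts


def fusion_fraction(counts: ClassCounts) -> float | None:
    """Fusion reads over all gene-B-containing reads
    (fusion / (fusion + solo_b)); None when the denominator is zero."""
    denom = counts.fusion + counts.solo_b
    if denom == 0:
        return None
    return counts.fusion / denom


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Transcripts-per-million per library (column): count / total * 1e6.

    Full-length reads are molecule counts, so no length correction is
    applied; each library column sums to 1e6 over the counted genes.
    """
    df = counts.astype(float)
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ParameterError(f"library with zero total counts: {bad}")
    return df / totals * 1e6
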