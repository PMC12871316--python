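"""Open reading frames, overlapping-frame logic, variant consequences and
tryptic peptides.

A fusion transcript that keeps two large reading frames can only encode a
single fused protein if the frames coincide; ORFs overlapping with a start
offset that is not a multiple of three are mutually exclusive. This module
finds ORFs on a transcript's sense strand, reports the frame relationship
of every overlapping pair, classifies variant consequences on a spliced
transcript (the reading-frame-maintenance check), and derives the tryptic
peptides that distinguish near-identical paralogous proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import InputError

__all__ = [
    "OrfRecord",
    "OrfPair",
    "TranscriptModel",
    "VariantConsequence",
    "PeptideSet",
    "find_orfs",
    "mutually_exclusive_orfs",
    "classify_variant",
    "tryptic_digest",
    "unique_peptides",
    "translate_orf",
]

STOPS = {"TAA", "TAG", "TGA"}
AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class OrfRecord:
    """A maximal ATG->stop reading frame on a transcript. ``end`` includes
    the stop codon; ``codons`` excludes it."""

    start: int
    end: int
    frame: int
    codons: int
    has_stop: bool = True


@dataclass(frozen=True)
class OrfPair:
    orf_i: OrfRecord
    orf_j: OrfRecord
    base_offset: int
    same_frame: bool
    mutually_exclusive: bool


@dataclass(frozen=True)
class VariantConsequence:
    position: int
    ref: str
    alt: str
    consequence: str  # synonymous | missense | stop_gained | frameshift | splice_site | stop_lost
    new_stop_position: int | None = None


@dataclass(frozen=True)
class PeptideSet:
    protein_id: str
    peptides: tuple  # (sequence, start, end) tiling the protein exactly


def find_orfs(transcript: str, min_codons: int = 50) -> list[OrfRecord]:
    """All maximal ORFs of at least ``min_codons`` codons, on the sense
    strand, in all three frames.

    Within a frame, each stop codon yields at most one record, anchored at
    the first ATG following the previous in-frame stop (the maximal ORF
    for that stop). Records are sorted by start. Open-ended runs without a
    stop are not reported.
    """
    bad = set(transcript) - set("ACGT")
    if bad:
        raise InputError(f"transcript contains non-ACGT symbols {sorted(bad)}")
    out = []
    n = len(transcript)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = transcript[i : i + 3]
            if codon in STOPS:
                if start is not None:
                    codons = (i + 3 - start) // 3 - 1
                    if codons >= min_codons:
                        out.append(OrfRecord(start, i + 3, start % 3, codons))
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return sorted(out, key=lambda o: (o.start, o.end))


def mutually_exclusive_orfs(orfs: list[OrfRecord]) -> list[OrfPair]:
    """Frame relationship of every overlapping ORF pair on one transcript.

    ``base_offset`` is the distance between the two start codons; the pair
    is in the same frame iff the offset is a multiple of three, and only
    same-frame overlaps could ever be translated as one fused product.
    """
    pairs = []
    ranked = sorted(orfs, key=lambda o: (o.start, o.end))
    for a_i, a in enumerate(ranked):
        for b in ranked[a_i + 1 :]:
            if b.start >= a.end:
                break
            offset = abs(a.start - b.start)
            same = offset % 3 == 0
            pairs.append(OrfPair(a, b, offset, same, not same))
    return pairs


# ---------------------------------------------------------------------------
# variant consequences on a spliced transcript


@dataclass
class TranscriptModel:
    """A plus-strand transcript on a genomic sequence: exon blocks plus the
    ORF (transcript coordinates) against which variants are interpreted."""

    genome: str
    blocks: list
    orf: OrfRecord

    def __post_init__(self):
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise InputError("blocks must be sorted and non-overlapping")

    @property
    def spliced(self) -> str:
        return "".join(self.genome[s:e] for s, e in self.blocks)

    def splice_dinucleotides(self):
        sites = []
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            sites.append((e1, e1 + 2))
            sites.append((s2 - 2, s2))
        return sites

    def to_transcript(self, genomic_pos: int) -> int | None:
        off = 0
        for s, e in self.blocks:
            if s <= genomic_pos < e:
                return off + (genomic_pos - s)
            off += e - s
        return None


def _protein(seq: str, start: int) -> str:
    coding = seq[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(to_stop=False))


def classify_variant(model: TranscriptModel, variant) -> VariantConsequence:
    """Classify one variant (genomic position, ref, alt) on the transcript.

    Splice-site variants (touching any donor/acceptor dinucleotide) take
    precedence. Exonic variants are applied to the spliced sequence:
    length changes not divisible by three are frameshifts; otherwise the
    mutant translation decides stop_gained (an earlier stop), stop_lost
    (the ORF's stop removed), missense, or synonymous. Variants outside
    both the ORF and the splice sites are synonymous (no protein change).
    """
    pos, ref, alt = variant
    ref, alt = ref.upper(), alt.upper()
    if model.genome[pos : pos + len(ref)] != ref:
        raise InputError(
            f"ref allele mismatch at {pos}: genome has "
            f"{model.genome[pos : pos + len(ref)]!r}, variant says {ref!r}"
        )
    var_span = range(pos, pos + max(len(ref), 1))
    for s, e in model.splice_dinucleotides():
        if any(s <= p < e for p in var_span):
            return VariantConsequence(pos, ref, alt, "splice_site")
    tpos = model.to_transcript(pos)
    if tpos is None:
        return VariantConsequence(pos, ref, alt, "synonymous")
    if (len(ref) - len(alt)) % 3 != 0:
        return VariantConsequence(pos, ref, alt, "frameshift")
    spliced = model.spliced
    mutant = spliced[:tpos] + alt + spliced[tpos + len(ref) :]
    orf = model.orf
    prot_ref = _protein(spliced, orf.start)
    prot_alt = _protein(mutant, orf.start)
    ref_stop = prot_ref.find("*")
    alt_stop = prot_alt.find("*")
    # an in-frame indel inside the ORF shifts where the original stop is
    # expected to reappear in the mutant translation
    delta = (len(alt) - len(ref)) // 3 if tpos < orf.start + 3 * max(ref_stop, 0) else 0
    expected = ref_stop + delta if ref_stop != -1 else -1
    if alt_stop != -1 and (expected == -1 or alt_stop < expected):
        return VariantConsequence(
            pos, ref, alt, "stop_gained", new_stop_position=orf.start + 3 * alt_stop
        )
    if expected != -1 and (alt_stop == -1 or alt_stop > expected):
        return VariantConsequence(pos, ref, alt, "stop_lost")
    upto_ref = ref_stop if ref_stop != -1 else len(prot_ref)
    upto_alt = expected if expected != -1 else len(prot_alt)
    if prot_alt[:upto_alt] != prot_ref[:upto_ref]:
        return VariantConsequence(pos, ref, alt, "missense")
    return VariantConsequence(pos, ref, alt, "synonymous")


# ---------------------------------------------------------------------------
# tryptic peptides


def tryptic_digest(protein: str, protein_id: str = "", missed_cleavages: int = 0) -> PeptideSet:
    """In-silico trypsin digest: cleave after K or R except before P.

    With ``missed_cleavages`` > 0, peptides spanning up to that many
    skipped sites are also emitted (fully-cleaved peptides always are).
    The fully-cleaved peptides tile the protein exactly.
    """
    bad = set(protein) - AA20
    if bad:
        raise InputError(f"invalid residues {sorted(bad)}")
    if not protein:
        raise InputError("empty protein")
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    base = [
        (protein[cuts[i] : cuts[i + 1]], cuts[i], cuts[i + 1])
        for i in range(len(cuts) - 1)
    ]
    peptides = list(base)
    for span in range(2, missed_cleavages + 2):
        for i in range(len(base) - span + 1):
            s, e = base[i][1], base[i + span - 1][2]
            peptides.append((protein[s:e], s, e))
    return PeptideSet(protein_id, tuple(peptides))


def unique_peptides(
    protein_a: str,
    protein_b: str,
    min_length: int = 7,
    background: list | None = None,
    missed_cleavages: int = 0,
):
    """Tryptic peptides (length >= min_length) found in one protein's
    digest and absent from the other's — the peptides that could identify
    each paralog in a mass-spectrometry search. Peptides also present in
    any ``background`` protein's digest are removed from both sides.
    Returns (unique_to_a, unique_to_b) as sorted lists of sequences."""
    pep_a = {p for p, _, _ in tryptic_digest(protein_a, "a", missed_cleavages).peptides}
    pep_b = {p for p, _, _ in tryptic_digest(protein_b, "b", missed_cleavages).peptides}
    bg = set()
    for prot in background or []:
        bg |= {p for p, _, _ in tryptic_digest(prot, "bg", missed_cleavages).peptides}
    ua = {p for p in pep_a - pep_b - bg if len(p) >= min_length}
    ub = {p for p in pep_b - pep_a - bg if len(p) >= min_length}
    return sorted(ua), sorted(ub)


def translate_orf(transcript: str, orf: OrfRecord) -> str:
    """Amino-acid sequence of an ORF (stop codon excluded)."""
    coding = transcript[orf.start : orf.end - 3] if orf.has_stop else transcript[orf.start : orf.end]
    return str(Seq(coding).translate(to_stop=False))
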