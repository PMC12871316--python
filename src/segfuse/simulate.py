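"""Synthetic study generator for a segmental-duplication gene cluster.

The generator emulates the regulatory architecture of a high-identity
tandem gene family in which the terminal copy sits downstream of a partial
duplicate of a second, promoter-bearing gene — the situation in which a
"position effect" drives most of the family's expression from one copy.
Concretely it builds, from a seed and explicit parameters:

* a single chromosome carrying ``n_paralogs`` near-identical copies of a
  ~10 kb gene-B cassette (14 exons, canonical GT..AG introns), the last of
  which is preceded by gene A, an 11-exon partial duplicate of an
  unrelated gene contributing its promoter;
* a fusion transcript architecture: splicing from the gene-A exon-10 donor
  to the gene-B exon-2 acceptor yields a transcript carrying two large
  overlapping reading frames in different frames (ORF1, 449 codons by
  default, ends 15 nt into exon B2; ORF2, 546 codons by default, starts
  2 nt into exon B2, hence 13 nt upstream of ORF1's end and offset by two
  bases from its frame) with a Kozak context (A-N-N-A-T-G-G) spanning the
  fusion acceptor site;
* solo gene-A transcripts that read through the exon-11 donor and
  terminate at an internal polyadenylation site 111 bp downstream, with
  the AATAAA hexamer planted within 20 bp of the 3' end;
* full-length transcript reads as a labelled mixture of solo-A, solo-B
  and fusion molecules with configurable substitution errors;
* per-CpG methylation calls with gene-body hypermethylation and a
  promoter dip only at the expressed (terminal) copy;
* windowed WGS depth proportional to per-region copy number.

Mutations between paralogs are independent per-base substitutions.
Functional elements (splice dinucleotides, the planted polyadenylation
hexamer, the Kozak context and ORF start/stop codons) are never mutated,
and by default mutations are resampled so they cannot create in-frame stop
codons inside the planted ORFs — the synthetic analogue of the observed
reading-frame maintenance across haplotypes (``protect_orfs=False``
disables this). Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from . import io as sfio

__all__ = [
    "SimConfig",
    "Paralog",
    "ParalogSet",
    "FusionGeneModel",
    "TranscriptRead",
    "CpGCall",
    "DepthTrack",
    "SOLO_A",
    "SOLO_B",
    "FUSION",
    "generate_paralog_set",
    "simulate_transcripts",
    "simulate_methylation",
    "simulate_depth",
    "simulate_study",
    "spliced_sequence",
    "fusion_transcript",
    "solo_a_transcript",
    "b_transcript",
    "reference_transcripts",
    "classification_model",
    "write_study",
]

SOLO_A = "SOLO_A"
SOLO_B = "SOLO_B"
FUSION = "FUSION"

CHROM = "chrSim"
_SPACER = 5200          # intergenic gap between copies; exceeds the default
_CASSETTE_HEAD = 300    # promoter-dip search window so silent-copy upstream
_CASSETTE_TAIL = 250    # windows only ever see intergenic methylation
_A_B_GAP = 200
_A_INTRON = 400
_B_INTRON = 620
_A_UTR5 = 45
_B_UTR3 = 47
_A_EXON11 = 120
_B_EXON1 = 100
_N_A_EXONS = 11
_N_B_EXONS = 14
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS61 = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# First 15 nt of exon B2, fixed: carries ORF1's four junction-crossing
# codons plus stop (CCA TGG CCC CCC TAA) and, offset by 2, ORF2's start
# (ATG GCC ...) completing the A-N-N-A-T-G-G Kozak context across the
# fusion acceptor.
_B2_PREFIX = "CCATGGCCCCCCTAA"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the downstream stages are exercised
    under: a four-copy cluster at 1% per-copy divergence (~2% pairwise,
    matching the high-identity segmental-duplication regime), 0.5% read
    substitution error, half of gene-B-containing molecules spliced as
    fusions, 30x CpG coverage and 30x WGS depth.
    """

    seed: int = 0
    n_paralogs: int = 4
    divergence: float = 0.01
    fusion_fraction: float = 0.5
    solo_a_fraction: float = 0.25
    single_exon_fraction: float = 0.0
    n_reads: int = 300
    read_error_rate: float = 0.005
    read_indel_rate: float = 0.0
    cpg_coverage_mean: float = 30.0
    depth_mean: float = 30.0
    depth_window_bp: int = 1000
    windows_per_region: int = 20
    copy_numbers: dict | None = None
    orf1_codons: int = 449
    orf2_codons: int = 546
    internal_polya_offset: int = 111
    protect_orfs: bool = True
    expressed_body_meth: float = 0.8
    silent_body_meth: float = 0.2
    promoter_dip_meth: float = 0.1
    intergenic_meth: float = 0.75
    beta_concentration: float = 20.0

    def __post_init__(self):
        for name in (
            "divergence",
            "fusion_fraction",
            "solo_a_fraction",
            "single_exon_fraction",
            "read_error_rate",
            "read_indel_rate",
            "expressed_body_meth",
            "silent_body_meth",
            "promoter_dip_meth",
            "intergenic_meth",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in ("n_paralogs", "n_reads", "depth_window_bp", "windows_per_region"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("cpg_coverage_mean", "depth_mean"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.orf1_codons < 6 or self.orf2_codons < 60:
            raise ParameterError("planted ORFs too short for the exon architecture")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass
class Paralog:
    id: str
    sequence: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class FusionGeneModel:
    """Paired gene models of the fused terminal locus (genomic, 0-based
    half-open, plus strand). ``merged_junction`` is (donor, acceptor): the
    3' end of gene-A exon 10 and the 5' end of gene-B exon 2."""

    chrom: str
    gene_a_exons: list
    gene_b_exons: list
    strand: str
    gene_a_tss: int
    gene_b_tss: int
    internal_polya_site: int
    merged_junction: tuple

    def __post_init__(self):
        for exons in (self.gene_a_exons, self.gene_b_exons):
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise InputError("exon intervals must be sorted and non-overlapping")
        donor, acceptor = self.merged_junction
        if not donor < acceptor:
            raise InputError("merged junction donor must precede acceptor")
        if self.gene_a_exons and not (donor <= self.internal_polya_site <= acceptor):
            raise InputError("internal polyA site must lie between donor and acceptor")


@dataclass
class ParalogSet:
    """The simulated family: per-copy cassette sequences and intervals on
    one chromosome, plus the truth needed downstream (variant positions,
    gene models per copy, the expressed copy's fused locus)."""

    chrom: str
    genome: str
    paralogs: list
    ancestral_id: str
    ancestral_cassette: str
    truth_variants: dict
    gene_b_exons_by_paralog: dict
    tss_by_paralog: dict
    tts_by_paralog: dict
    expressed_paralog: str
    fusion_model: FusionGeneModel
    promoter_interval: tuple
    config: SimConfig

    def paralog_ids(self):
        return [p.id for p in self.paralogs]


@dataclass
class TranscriptRead:
    id: str
    sequence: str
    truth_paralog: str
    truth_class: str
    truth_blocks: list
    strand: str = "+"


@dataclass(frozen=True)
class CpGCall:
    position: int
    coverage: int
    methylated: int

    def __post_init__(self):
        if not 0 <= self.methylated <= self.coverage:
            raise InputError(
                f"methylated ({self.methylated}) exceeds coverage ({self.coverage})"
            )


@dataclass
class DepthTrack:
    """Windowed read-start counts per region plus the designated unique
    diploid control regions."""

    windows: pd.DataFrame  # region, chrom, start, end, count
    control_regions: list
    truth_cn: dict | None = None


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_bases(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _scrub(seq: str, motif: str = "ATG") -> str:
    """Remove every occurrence of ``motif`` by rewriting its last base to C
    (cannot create a new ATG)."""
    while motif in seq:
        i = seq.index(motif)
        seq = seq[: i + len(motif) - 1] + "C" + seq[i + len(motif) :]
    return seq


def _noncoding(rng, n: int) -> str:
    return _scrub(_random_bases(rng, n))


def _random_codons(rng, n: int) -> str:
    return "".join(np.array(_CODONS61)[rng.integers(0, 61, n)])


def _intron(rng, n: int) -> str:
    if n < 4:
        raise ParameterError("introns must be at least 4 bp")
    return "GT" + _noncoding(rng, n - 4) + "AG"


def _split_lengths(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    out[-1] += total - base * parts
    return out


def _slice_into(coding: str, lengths: list[int]) -> list[str]:
    out, i = [], 0
    for n in lengths:
        out.append(coding[i : i + n])
        i += n
    return out


def _build_cassette(rng, cfg: SimConfig):
    """Ancestral gene-B cassette: head | B1 | (intron exon)*13 | tail.

    Returns (sequence, exon intervals, ORF2 coding->genomic map,
    protected positions) with coordinates relative to the cassette.
    """
    orf2_len = cfg.orf2_codons * 3 + 3
    span_2_14 = 2 + orf2_len + _B_UTR3
    lengths = _split_lengths(span_2_14, _N_B_EXONS - 1)
    if lengths[0] < len(_B2_PREFIX) + 3:
        raise ParameterError("orf2_codons too small for the 13-exon layout")
    # ORF2 body after the fixed prefix: completes the prefix's partial codon
    # then runs non-stop codons to a planted TAA.
    tail_len = orf2_len - 13  # prefix carries ORF2's first 13 nt
    n_free = (tail_len - 2 - 3) // 3
    coding = _B2_PREFIX + _random_bases(rng, 2) + _random_codons(rng, n_free) + "TAA"
    utr3 = _noncoding(rng, _B_UTR3)
    # plant the canonical polyA hexamer ending 5 nt before the transcript end
    utr3 = utr3[:-11] + "AATAAA" + utr3[-5:]
    utr3 = _scrub(utr3)  # scrub cannot touch AATAAA (no ATG overlap survives)
    payload = coding + utr3
    exon_seqs = [_noncoding(rng, _B_EXON1 - 1) + "A"] + _slice_into(payload, lengths)
    parts = [_noncoding(rng, _CASSETTE_HEAD)]
    exons = []
    pos = _CASSETTE_HEAD
    for i, es in enumerate(exon_seqs):
        if i > 0:
            parts.append(_intron(rng, _B_INTRON))
            pos += _B_INTRON
        parts.append(es)
        exons.append((pos, pos + len(es)))
        pos += len(es)
    parts.append(_noncoding(rng, _CASSETTE_TAIL))
    seq = "".join(parts)

    # spliced offset (within exons B2..B14) -> cassette position
    spliced_to_pos = []
    for s, e in exons[1:]:
        spliced_to_pos.extend(range(s, e))
    orf2_map = {k - 2: spliced_to_pos[k] for k in range(2, 2 + orf2_len)}

    protected = set()
    for (s, _), (_, e_prev) in zip(exons[1:], exons[:-1]):
        protected.update((e_prev, e_prev + 1, s - 2, s - 1))  # GT..AG per intron
    b2s = exons[1][0]
    protected.update(range(b2s, b2s + len(_B2_PREFIX)))  # junction codons + Kozak
    protected.add(exons[0][1] - 1)  # B1 terminal A (solo-B Kozak context)
    protected.update(spliced_to_pos[2 + orf2_len - 3 : 2 + orf2_len])
    motif_end = exons[-1][1] - 5
    protected.update(range(motif_end - 6, motif_end))  # planted AATAAA
    return seq, exons, orf2_map, protected


def _build_gene_a(rng, cfg: SimConfig):
    """Gene A region: 11 exons; exons 1-10 carry ORF1's in-A coding, exon 11
    plus 111 bp of readthrough host the internal polyA site."""
    a_coding_len = cfg.orf1_codons * 3 - 12  # ORF1 minus its four in-B codons
    # last two codons fixed (GCT GAA): keeps ORF2's frame stop-free and ATG-free
    # across the junction and puts the Kozak A at the donor's last base
    coding = "ATG" + _random_codons(rng, (a_coding_len - 9) // 3) + "GCTGAA"
    total_1_10 = _A_UTR5 + a_coding_len
    lengths = _split_lengths(total_1_10, _N_A_EXONS - 1)
    utr5 = _noncoding(rng, _A_UTR5 - 3) + "TAA"  # in-frame stop guards ORF1's ATG
    payload = utr5 + coding
    exon_seqs = _slice_into(payload, lengths) + [_noncoding(rng, _A_EXON11)]
    parts, exons, pos = [], [], 0
    for i, es in enumerate(exon_seqs):
        if i > 0:
            parts.append(_intron(rng, _A_INTRON))
            pos += _A_INTRON
        parts.append(es)
        exons.append((pos, pos + len(es)))
        pos += len(es)
    # readthrough past the exon-11 donor: GT, then the internal polyA site
    # internal_polya_offset bp downstream with AATAAA ending 5 nt before it
    rt = "GT" + _noncoding(rng, cfg.internal_polya_offset - 2)
    rt = rt[:-11] + "AATAAA" + rt[-5:]
    parts.append(rt)
    seq = "".join(parts)
    polya_site = pos + cfg.internal_polya_offset
    return seq, exons, polya_site


def _mutate_cassette(rng, seq: str, rate: float, protected: set, orf2_map: dict,
                     protect_orfs: bool):
    """Independent per-base substitution, uniform over the three
    alternatives; protected positions are exempt and (by default) proposals
    creating an in-frame ORF2 stop are redirected to a harmless base."""
    if rate == 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.shape[0]
    hits = np.flatnonzero(rng.random(n) < rate)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    pos_to_orf2 = orf2_map if protect_orfs else {}
    coding_arr = None
    if protect_orfs:
        inv = sorted(orf2_map.items())
        coding_arr = np.array([seq[p] for _, p in inv])
        pos_to_orf2 = {p: k for k, p in orf2_map.items()}
    variants = []
    for p in hits:
        p = int(p)
        if p in protected:
            continue
        ref = chr(arr[p])
        choices = [b for b in "ACGT" if b != ref]
        alt = choices[int(rng.integers(0, 3))]
        if protect_orfs and p in pos_to_orf2:
            k = pos_to_orf2[p]
            c0 = k - k % 3
            ok = []
            for cand in choices:
                codon = "".join(
                    cand if c0 + j == k else coding_arr[c0 + j] for j in range(3)
                )
                if codon not in _STOPS:
                    ok.append(cand)
            if not ok:
                continue
            if alt not in ok:
                alt = ok[int(rng.integers(0, len(ok)))]
            coding_arr[k] = alt
        arr[p] = ord(alt)
        variants.append((p, ref, alt))
    return arr.tobytes().decode(), variants


def generate_paralog_set(config: SimConfig) -> ParalogSet:
    """Build the cluster: ``n_paralogs`` independently mutated copies of one
    ancestral cassette in tandem, gene A fused upstream of the last copy."""
    rng_seq = config.rng(0)
    rng_mut = config.rng(1)
    cassette, b_exons, orf2_map, protected = _build_cassette(rng_seq, config)
    gene_a_seq, a_exons_local, polya_local = _build_gene_a(rng_seq, config)

    copies, variants = [], {}
    for i in range(config.n_paralogs):
        mutated, var = _mutate_cassette(
            rng_mut, cassette, config.divergence, protected, orf2_map,
            config.protect_orfs,
        )
        pid = f"paralog_{i + 1}"
        copies.append((pid, mutated))
        variants[pid] = var

    parts, pos = [], 0
    paralogs, b_exons_by, tss_by, tts_by = [], {}, {}, {}
    spacer = _noncoding(rng_seq, _SPACER)

    def _push(s):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    _push(spacer)
    gene_a_exons = None
    polya_site = None
    for i, (pid, cseq) in enumerate(copies):
        terminal = i == config.n_paralogs - 1
        if terminal:
            a_start = pos
            _push(gene_a_seq)
            gene_a_exons = [(a_start + s, a_start + e) for s, e in a_exons_local]
            polya_site = a_start + polya_local
            _push(_noncoding(rng_seq, _A_B_GAP))
        cstart = pos
        _push(cseq)
        paralogs.append(Paralog(pid, cseq, cstart, pos))
        b_exons_by[pid] = [(cstart + s, cstart + e) for s, e in b_exons]
        tss_by[pid] = gene_a_exons[0][0] if terminal else b_exons_by[pid][0][0]
        tts_by[pid] = b_exons_by[pid][-1][1]
        if not terminal:
            _push(_noncoding(rng_seq, _SPACER))
    _push(spacer[::-1])
    genome = "".join(parts)

    expressed = copies[-1][0]
    model = FusionGeneModel(
        chrom=CHROM,
        gene_a_exons=gene_a_exons,
        gene_b_exons=b_exons_by[expressed],
        strand="+",
        gene_a_tss=gene_a_exons[0][0],
        gene_b_tss=b_exons_by[expressed][0][0],
        internal_polya_site=polya_site,
        merged_junction=(gene_a_exons[9][1], b_exons_by[expressed][1][0]),
    )
    tss_a = gene_a_exons[0][0]
    return ParalogSet(
        chrom=CHROM,
        genome=genome,
        paralogs=paralogs,
        ancestral_id="ancestral",
        ancestral_cassette=cassette,
        truth_variants=variants,
        gene_b_exons_by_paralog=b_exons_by,
        tss_by_paralog=tss_by,
        tts_by_paralog=tts_by,
        expressed_paralog=expressed,
        fusion_model=model,
        promoter_interval=(tss_a - 500, tss_a + 100),
        config=config,
    )


# ---------------------------------------------------------------------------
# transcripts


def spliced_sequence(genome: str, blocks) -> str:
    return "".join(genome[s:e] for s, e in blocks)


def _fusion_blocks(ps: ParalogSet):
    m = ps.fusion_model
    return m.gene_a_exons[:10] + m.gene_b_exons[1:]


def _solo_a_blocks(ps: ParalogSet):
    m = ps.fusion_model
    e11 = m.gene_a_exons[10]
    return m.gene_a_exons[:10] + [(e11[0], m.internal_polya_site)]


def fusion_transcript(ps: ParalogSet) -> str:
    """The fused-locus transcript: gene-A exons 1-10 spliced to gene-B
    exons 2-14 of the expressed copy."""
    return spliced_sequence(ps.genome, _fusion_blocks(ps))


def solo_a_transcript(ps: ParalogSet) -> str:
    return spliced_sequence(ps.genome, _solo_a_blocks(ps))


def b_transcript(ps: ParalogSet, paralog_id: str) -> str:
    return spliced_sequence(ps.genome, ps.gene_b_exons_by_paralog[paralog_id])


def reference_transcripts(ps: ParalogSet) -> dict:
    """Per-paralog reference transcripts for assignment: each copy's solo
    gene-B isoform; the expressed copy additionally contributes the fusion
    isoform (a read scores a paralog by its best isoform)."""
    refs = {pid: [b_transcript(ps, pid)] for pid in ps.paralog_ids()}
    refs[ps.expressed_paralog].append(fusion_transcript(ps))
    return refs


def classification_model(ps: ParalogSet) -> FusionGeneModel:
    """Classification view of the locus: gene-B exons pooled across all
    copies, so solo-B molecules from any paralog are recognised."""
    all_b = sorted(ex for pid in ps.paralog_ids() for ex in ps.gene_b_exons_by_paralog[pid])
    m = ps.fusion_model
    return replace(m, gene_b_exons=all_b)


def _apply_read_errors(rng, seq: str, sub_rate: float, indel_rate: float) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return seq
    arr = list(seq)
    if sub_rate > 0:
        for p in np.flatnonzero(rng.random(len(arr)) < sub_rate):
            ref = arr[p]
            arr[p] = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
    if indel_rate > 0:
        out = []
        for b in arr:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(b)
            if r > 1 - indel_rate / 2:
                out.append("ACGT"[int(rng.integers(0, 4))])
        arr = out
    return "".join(arr)


def simulate_transcripts(ps: ParalogSet, model: FusionGeneModel, config: SimConfig):
    """Draw labelled full-length reads.

    Classes: solo-A with probability ``solo_a_fraction``; the remaining
    (gene-B-containing) reads are fusions with probability
    ``fusion_fraction``, else solo-B. Solo-A and fusion molecules originate
    from the expressed copy; solo-B molecules are drawn uniformly across
    copies. A ``single_exon_fraction`` of reads is truncated to one random
    exon block (the contamination the single-exon exclusion removes).
    """
    rng = config.rng(2)
    reads = []
    pids = ps.paralog_ids()
    for i in range(config.n_reads):
        u = rng.random()
        if u < config.solo_a_fraction:
            cls, pid = SOLO_A, ps.expressed_paralog
            blocks = _solo_a_blocks(ps)
        elif rng.random() < config.fusion_fraction:
            cls, pid = FUSION, ps.expressed_paralog
            blocks = _fusion_blocks(ps)
        else:
            cls = SOLO_B
            pid = pids[int(rng.integers(0, len(pids)))]
            blocks = list(ps.gene_b_exons_by_paralog[pid])
        if config.single_exon_fraction > 0 and rng.random() < config.single_exon_fraction:
            blocks = [blocks[int(rng.integers(0, len(blocks)))]]
        seq = _apply_read_errors(
            rng,
            spliced_sequence(ps.genome, blocks),
            config.read_error_rate,
            config.read_indel_rate,
        )
        reads.append(
            TranscriptRead(f"read_{i:05d}", seq, pid, cls, blocks)
        )
    return reads


# ---------------------------------------------------------------------------
# methylation


def _beta_params(mean: float, conc: float):
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    return mean * conc, (1 - mean) * conc


def simulate_methylation(ps: ParalogSet, expressed_paralog: str, config: SimConfig):
    """Per-CpG calls over the cluster chromosome.

    The expressed copy's gene body (its TSS through the shared TTS) is
    hypermethylated with a hypomethylated promoter window at the TSS;
    silent copies get uniformly low gene-body methylation and no dip;
    everything else sits at the intergenic background. Coverage is
    Poisson(``cpg_coverage_mean``); zero-coverage sites are not reported.
    """
    if expressed_paralog not in ps.tss_by_paralog:
        raise InputError(f"unknown paralog id {expressed_paralog!r}")
    rng = config.rng(3)
    arr = np.frombuffer(ps.genome.encode(), dtype=np.uint8)
    positions = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    if config.cpg_coverage_mean == 0 or positions.size == 0:
        return []
    means = np.full(positions.size, config.intergenic_meth)
    for pid in ps.paralog_ids():
        lo, hi = ps.tss_by_paralog[pid], ps.tts_by_paralog[pid]
        inside = (positions >= lo) & (positions < hi)
        level = (
            config.expressed_body_meth
            if pid == expressed_paralog
            else config.silent_body_meth
        )
        means[inside] = level
    tss = ps.tss_by_paralog[expressed_paralog]
    dlo, dhi = tss - 500, tss + 100
    means[(positions >= dlo) & (positions < dhi)] = config.promoter_dip_meth
    conc = config.beta_concentration
    calls = []
    cov = rng.poisson(config.cpg_coverage_mean, positions.size)
    for pos, c, mu in zip(positions, cov, means):
        if c == 0:
            continue
        a, b = _beta_params(mu, conc)
        p = rng.beta(a, b)
        calls.append(CpGCall(int(pos), int(c), int(rng.binomial(c, p))))
    return calls


# ---------------------------------------------------------------------------
# depth


def default_copy_numbers(config: SimConfig) -> dict:
    return {
        "gene_b_cluster": 2 * config.n_paralogs,
        "gene_a": 2,
        "gene_a_promoter": 2,
    }


def simulate_depth(ps: ParalogSet, config: SimConfig) -> DepthTrack:
    """Windowed WGS depth: counts ~ Poisson(depth_mean * CN / 2) per
    window, laid out region by region on a synthetic depth contig, plus
    two unique-diploid control regions (CN=2)."""
    rng = config.rng(4)
    cn = dict(config.copy_numbers or default_copy_numbers(config))
    controls = [k for k in cn if k.startswith("control")]
    if not controls:
        cn["control_1"] = 2
        cn["control_2"] = 2
        controls = ["control_1", "control_2"]
    if not any(cn[k] == 2 for k in controls):
        raise ParameterError("at least one control region with CN=2 is required")
    rows = []
    pos = 0
    for region, c in sorted(cn.items()):
        if c < 0:
            raise ParameterError(f"copy number for {region} must be >= 0")
        counts = rng.poisson(config.depth_mean * c / 2.0, config.windows_per_region)
        for w, k in enumerate(counts):
            start = pos + w * config.depth_window_bp
            rows.append(
                {
                    "region": region,
                    "chrom": "chrDepth",
                    "start": start,
                    "end": start + config.depth_window_bp,
                    "count": int(k),
                }
            )
        pos += config.windows_per_region * config.depth_window_bp
    return DepthTrack(pd.DataFrame(rows), controls, truth_cn=cn)


# ---------------------------------------------------------------------------
# bundle + emitters


@dataclass
class SyntheticStudy:
    config: SimConfig
    paralog_set: ParalogSet
    model: FusionGeneModel
    reads: list
    methylation: list
    depth: DepthTrack


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Run every generator under one config; the one-call entry point."""
    ps = generate_paralog_set(config)
    reads = simulate_transcripts(ps, ps.fusion_model, config)
    meth = simulate_methylation(ps, ps.expressed_paralog, config)
    depth = simulate_depth(ps, config)
    return SyntheticStudy(config, ps, ps.fusion_model, reads, meth, depth)


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Emit the study as plain files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    ps = study.paralog_set
    seed = cfg.seed
    paths = {k: out / v for k, v in {
        "genome": "genome.fa",
        "paralogs": "paralogs.fa",
        "reads": "reads.fa",
        "gene_models": "gene_models.bed12",
        "read_blocks": "read_blocks.bed12",
        "methylation": "methylation.tsv",
        "depth": "depth.tsv",
        "truth": "truth.json",
    }.items()}
    sfio.write_fasta([(ps.chrom, "synthetic cluster", ps.genome)], paths["genome"], seed)
    sfio.write_fasta(
        [(p.id, f"locus {ps.chrom}:{p.start}-{p.end}", p.sequence) for p in ps.paralogs],
        paths["paralogs"],
        seed,
    )
    sfio.write_fasta(
        [(r.id, f"{r.truth_class} {r.truth_paralog}", r.sequence) for r in study.reads],
        paths["reads"],
        seed,
    )
    m = study.model
    gene_rows = [
        {
            "chrom": ps.chrom, "start": m.gene_a_exons[0][0], "end": m.gene_a_exons[-1][1],
            "name": "gene_a", "strand": m.strand, "blocks": m.gene_a_exons,
        }
    ] + [
        {
            "chrom": ps.chrom,
            "start": ps.gene_b_exons_by_paralog[pid][0][0],
            "end": ps.gene_b_exons_by_paralog[pid][-1][1],
            "name": f"gene_b|{pid}",
            "strand": m.strand,
            "blocks": ps.gene_b_exons_by_paralog[pid],
        }
        for pid in ps.paralog_ids()
    ]
    sfio.write_bed12(gene_rows, paths["gene_models"], seed)
    sfio.write_bed12(
        [
            {
                "chrom": ps.chrom, "start": r.truth_blocks[0][0],
                "end": r.truth_blocks[-1][1], "name": r.id, "strand": r.strand,
                "blocks": r.truth_blocks,
            }
            for r in study.reads
        ],
        paths["read_blocks"],
        seed,
    )
    meth_df = pd.DataFrame(
        [
            {
                "chrom": ps.chrom, "start": c.position, "end": c.position + 2,
                "coverage": c.coverage,
                "percent_methylated": round(100.0 * c.methylated / c.coverage, 2),
                "methylated": c.methylated,
            }
            for c in study.methylation
        ]
    )
    sfio.write_methyl_tsv(meth_df, paths["methylation"], seed)
    sfio.write_depth_tsv(study.depth.windows, paths["depth"], seed)
    truth = {
        "seed": seed,
        "expressed_paralog": ps.expressed_paralog,
        "paralogs": {
            p.id: {"start": p.start, "end": p.end, "n_variants": len(ps.truth_variants[p.id])}
            for p in ps.paralogs
        },
        "reads": {r.id: {"class": r.truth_class, "paralog": r.truth_paralog} for r in study.reads},
        "internal_polya_site": m.internal_polya_site,
        "merged_junction": list(m.merged_junction),
        "promoter_interval": list(ps.promoter_interval),
        "copy_numbers": study.depth.truth_cn,
        "control_regions": study.depth.control_regions,
    }
    sfio.write_json(truth, paths["truth"])
    return paths
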