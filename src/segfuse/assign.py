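"""Paralog assignment by the strict best-over-second-best score rule.

A read is attributed to a paralog only when its best alignment score
strictly exceeds the runner-up; any tie at the top — including the
degenerate case of identical references — leaves the read AMBIGUOUS.
Scores come either from the built-in local aligner (see
:mod:`segfuse.align`) or from precomputed SAM ``AS`` tags / TSV tables, so
externally aligned data drop into the same rule. Fractional external
scores are floored to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
import pysam

from .align import ScoringParams, _kmer_index, seeded_score
from .errors import InputError

__all__ = [
    "AMBIGUOUS",
    "ScoredCandidate",
    "Assignment",
    "assign_read",
    "assign_all",
    "candidates_from_sam",
    "candidates_from_tsv",
    "assignments_to_frame",
]

AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ScoredCandidate:
    read_id: str
    paralog_id: str
    score: int
    is_primary: bool = False


@dataclass(frozen=True)
class Assignment:
    read_id: str
    assigned_paralog: str  # paralog id or AMBIGUOUS
    best_score: int
    second_score: float  # -inf with a single candidate
    margin: float


def assign_read(candidates: list[ScoredCandidate]) -> Assignment:
    """Apply the strict rule to one read's scored candidates.

    With a single candidate the second-best score is negative infinity and
    the read is assigned. Two or more candidates tied at the top are
    AMBIGUOUS no matter how many.
    """
    if not candidates:
        raise InputError("assign_read requires at least one candidate")
    read_id = candidates[0].read_id
    ranked = sorted(candidates, key=lambda c: -c.score)
    best = ranked[0]
    second = ranked[1].score if len(ranked) > 1 else -math.inf
    margin = best.score - second
    if margin > 0:
        return Assignment(read_id, best.paralog_id, best.score, second, margin)
    return Assignment(read_id, AMBIGUOUS, best.score, second, 0.0)


def assign_all(
    reads,
    references: dict,
    params: ScoringParams = ScoringParams(),
    *,
    band: int = 64,
    single_exon_ids: set | None = None,
):
    """Score every read against every paralog and apply the strict rule.

    ``reads`` maps read id -> sequence; ``references`` maps paralog id to
    one reference sequence or a list of isoform references (a paralog is
    scored by its best isoform). Returns (assignments, counts) where
    counts tallies assigned reads per paralog, excluding AMBIGUOUS reads
    and any read in ``single_exon_ids`` (the single-exon exclusion applied
    at the counting step).
    """
    if not references:
        raise InputError("assign_all requires at least one reference")
    if isinstance(reads, list):
        reads = {r.id: r.sequence for r in reads}
    refs = {
        pid: [seqs] if isinstance(seqs, str) else list(seqs)
        for pid, seqs in references.items()
    }
    indexes = {
        pid: [(seq, _kmer_index(seq, 21)) for seq in seqs] for pid, seqs in refs.items()
    }
    single_exon_ids = single_exon_ids or set()
    assignments = []
    counts = {pid: 0 for pid in refs}
    for rid, seq in reads.items():
        cands = []
        for pid, isoforms in indexes.items():
            score = max(
                seeded_score(seq, ref, params, band=band, ref_index=idx)
                for ref, idx in isoforms
            )
            cands.append(ScoredCandidate(rid, pid, score))
        a = assign_read(cands)
        assignments.append(a)
        if a.assigned_paralog != AMBIGUOUS and rid not in single_exon_ids:
            counts[a.assigned_paralog] += 1
    return assignments, counts


def candidates_from_sam(path) -> dict:
    """Read alignment-score candidates from a (headered) SAM file's AS
    tags; returns read id -> list of ScoredCandidate. Unmapped records are
    skipped; scores are floored to integers."""
    out: dict = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            if not rec.has_tag("AS"):
                continue
            cand = ScoredCandidate(
                rec.query_name,
                rec.reference_name,
                math.floor(rec.get_tag("AS")),
                is_primary=not (rec.is_secondary or rec.is_supplementary),
            )
            out.setdefault(rec.query_name, []).append(cand)
    return out


def candidates_from_tsv(path) -> dict:
    """TSV alternative: columns read_id, paralog_id, score[, is_primary]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"read_id", "paralog_id", "score"}
    if not required <= set(df.columns):
        raise InputError(f"candidate table missing columns {required - set(df.columns)}")
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.read_id), []).append(
            ScoredCandidate(
                str(row.read_id),
                str(row.paralog_id),
                math.floor(row.score),
                bool(getattr(row, "is_primary", False)),
            )
        )
    return out


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "assigned_paralog": a.assigned_paralog,
                "best_score": a.best_score,
                "second_score": a.second_score,
                "margin": a.margin,
            }
            for a in assignments
        ]
    )
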