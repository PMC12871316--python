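"""End-to-end orchestration: simulate -> assign -> classify -> motifs ->
methylation -> coding -> copy number, with a JSON summary.

Every stage writes plain files into the run directory and the summary
collects each stage's headline numbers plus truth-vs-estimate recovery
metrics (the study is synthetic, so the truth is known). Two runs with the
same configuration produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sfio
from .align import ScoringParams
from .assign import AMBIGUOUS, assign_all, assignments_to_frame
from .classify import (
    ReadBlocks,
    classify_read,
    count_classes,
    fusion_fraction,
    tpm_normalize,
)
from .cn import estimate_all
from .coding import find_orfs, mutually_exclusive_orfs, translate_orf, unique_peptides
from .errors import ParameterError
from .methylation import (
    aggregate_and_filter,
    detect_promoter_dip,
    gene_body_methylation,
    smooth_track,
)
from .motifs import find_kozak, find_polya, validate_junctions
from .simulate import (
    FUSION,
    SOLO_A,
    SOLO_B,
    SimConfig,
    b_transcript,
    classification_model,
    fusion_transcript,
    reference_transcripts,
    simulate_study,
    write_study,
)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "assign", "classify", "motifs", "methyl", "coding", "cn")


@dataclass
class RunConfig:
    """Pipeline configuration: the simulation parameters, stage toggles and
    the output directory. The serialised config is stored alongside the
    outputs so a run can be reproduced from its directory alone."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "segfuse_run"
    stages: tuple = _STAGES
    min_exon_overlap: int = 10
    band: int = 64
    dip_threshold: float = 0.25
    dip_min_run: int = 5
    dip_search_bp: int = 5000
    min_orf_codons: int = 50
    peptide_min_length: int = 7

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ParameterError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        try:
            return cls(sim=sim, **d)
        except TypeError as exc:
            raise ParameterError(str(exc)) from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _round(x, nd=6):
    return None if x is None else round(float(x), nd)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the
    summary dict (also written to ``<outdir>/summary.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sfio.write_json(config.to_dict(), out / "config.json")
    cfg = config.sim
    stages = set(config.stages)

    study = simulate_study(cfg)
    ps = study.paralog_set
    summary: dict = {
        "seed": cfg.seed,
        "stages": sorted(stages),
        "n_paralogs": cfg.n_paralogs,
        "n_reads": len(study.reads),
    }
    if "simulate" in stages:
        write_study(study, out)
        summary["simulate"] = {
            "genome_bp": len(ps.genome),
            "expressed_paralog": ps.expressed_paralog,
            "truth_classes": {
                c: sum(r.truth_class == c for r in study.reads)
                for c in (SOLO_A, SOLO_B, FUSION)
            },
        }

    truth_class = {r.id: r.truth_class for r in study.reads}
    truth_paralog = {r.id: r.truth_paralog for r in study.reads}

    if "assign" in stages:
        refs = reference_transcripts(ps)
        single_exon = {r.id for r in study.reads if len(r.truth_blocks) == 1}
        assignments, counts = assign_all(
            study.reads, refs, ScoringParams(), band=config.band,
            single_exon_ids=single_exon,
        )
        adf = assignments_to_frame(assignments)
        adf.to_csv(out / "assignments.tsv", sep="\t", index=False)
        decided = [a for a in assignments if a.assigned_paralog != AMBIGUOUS]
        correct = sum(a.assigned_paralog == truth_paralog[a.read_id] for a in decided)
        summary["assignment"] = {
            "per_paralog_counts": counts,
            "n_ambiguous": len(assignments) - len(decided),
            "accuracy_vs_truth": _round(correct / len(decided)) if decided else None,
        }

    model = classification_model(ps)
    read_blocks = {
        r.id: ReadBlocks(r.id, ps.chrom, tuple(r.truth_blocks), r.strand)
        for r in study.reads
    }
    if "classify" in stages:
        classes = {
            rid: classify_read(rb, model, config.min_exon_overlap)
            for rid, rb in read_blocks.items()
        }
        pd.DataFrame(
            [{"read_id": rid, "class": c, "truth": truth_class[rid]} for rid, c in classes.items()]
        ).to_csv(out / "classes.tsv", sep="\t", index=False)
        counts = count_classes(classes.values())
        frac = fusion_fraction(counts)
        tpm = tpm_normalize(
            pd.DataFrame(
                {"library_1": {"gene_a_solo": counts.solo_a, "gene_b_solo": counts.solo_b,
                               "fusion": counts.fusion}}
            )
        )
        tpm.to_csv(out / "tpm.tsv", sep="\t")
        truth_frac_den = sum(c in (FUSION, SOLO_B) for c in truth_class.values())
        truth_frac = (
            sum(c == FUSION for c in truth_class.values()) / truth_frac_den
            if truth_frac_den
            else None
        )
        summary["classification"] = {
            "counts": dataclasses.asdict(counts),
            "fusion_fraction": _round(frac),
            "truth_fusion_fraction": _round(truth_frac),
            "abs_error_vs_truth": _round(abs(frac - truth_frac))
            if frac is not None and truth_frac is not None
            else None,
            "tpm": {g: _round(v) for g, v in tpm["library_1"].items()},
        }

    if "motifs" in stages:
        polya_rows, junction_rows = [], []
        for r in study.reads:
            rb = read_blocks[r.id]
            end = rb.blocks[-1][1] if r.strand == "+" else rb.blocks[0][0]
            hit = find_polya(r.id, end, ps.genome, r.strand)
            polya_rows.append(
                {
                    "read_id": r.id,
                    "found": hit is not None,
                    "position": hit.position if hit else None,
                    "distance_from_end": hit.distance_from_end if hit else None,
                }
            )
            for jc in validate_junctions(rb, ps.genome):
                junction_rows.append(
                    {
                        "read_id": r.id,
                        "donor_position": jc.donor_position,
                        "acceptor_position": jc.acceptor_position,
                        "donor": jc.donor_dinucleotide,
                        "acceptor": jc.acceptor_dinucleotide,
                        "canonical": jc.canonical,
                    }
                )
        pdf = pd.DataFrame(polya_rows)
        jdf = pd.DataFrame(junction_rows)
        pdf.to_csv(out / "polya.tsv", sep="\t", index=False)
        jdf.to_csv(out / "junctions.tsv", sep="\t", index=False)
        summary["motifs"] = {
            "polya_detection_rate": _round(pdf["found"].mean()),
            "n_junctions": int(len(jdf)),
            "canonical_junction_fraction": _round(jdf["canonical"].mean())
            if len(jdf)
            else None,
        }

    if "methyl" in stages:
        track = smooth_track(aggregate_and_filter(study.methylation))
        body_rows, dip_rows = [], []
        for pid in ps.paralog_ids():
            mean, n = gene_body_methylation(
                track, (ps.tss_by_paralog[pid], ps.tts_by_paralog[pid])
            )
            body_rows.append({"paralog": pid, "gene_body_mean": _round(mean), "n_cpgs": n})
            call = detect_promoter_dip(
                track,
                ps.tss_by_paralog[pid],
                "+",
                config.dip_search_bp,
                config.dip_threshold,
                config.dip_min_run,
                paralog_id=pid,
            )
            dip_rows.append(
                {
                    "paralog": pid,
                    "called": bool(call and call.called),
                    "dip_start": call.dip_start if call else None,
                    "dip_end": call.dip_end if call else None,
                    "min_smoothed": _round(call.min_smoothed) if call else None,
                    "flank_level": _round(call.flank_level) if call else None,
                }
            )
        pd.DataFrame(body_rows).to_csv(out / "gene_body_methylation.tsv", sep="\t", index=False)
        pd.DataFrame(dip_rows).to_csv(out / "promoter_calls.tsv", sep="\t", index=False)
        called = [r["paralog"] for r in dip_rows if r["called"]]
        summary["methylation"] = {
            "retained_cpgs": len(track),
            "gene_body": {r["paralog"]: r["gene_body_mean"] for r in body_rows},
            "promoter_calls": called,
            "single_promoter_architecture": called == [ps.expressed_paralog],
        }

    if "coding" in stages:
        ftx = fusion_transcript(ps)
        orfs = find_orfs(ftx, config.min_orf_codons)
        pairs = mutually_exclusive_orfs(orfs)
        orf_rows = [dataclasses.asdict(o) for o in orfs]
        pd.DataFrame(orf_rows).to_csv(out / "orfs.tsv", sep="\t", index=False)
        two_largest = sorted(orfs, key=lambda o: -o.codons)[:2]
        kozak = find_kozak(ftx)
        # paralog-distinguishing peptides: the expressed copy's gene-B ORF
        # against the first internal copy's
        def _orf2_protein(pid):
            tx = b_transcript(ps, pid)
            cands = [o for o in find_orfs(tx, config.min_orf_codons)]
            return translate_orf(tx, max(cands, key=lambda o: o.codons))
        ua, ub = unique_peptides(
            _orf2_protein(ps.expressed_paralog),
            _orf2_protein(ps.paralog_ids()[0]),
            min_length=config.peptide_min_length,
        )
        summary["coding"] = {
            "n_orfs": len(orfs),
            "largest_orf_codons": [o.codons for o in two_largest],
            "n_mutually_exclusive_pairs": sum(p.mutually_exclusive for p in pairs),
            "kozak_sites": [k.position for k in kozak],
            "unique_peptides_expressed": len(ua),
            "unique_peptides_internal": len(ub),
        }

    if "cn" in stages:
        cn_df = estimate_all(study.depth)
        cn_df.to_csv(out / "copy_number.tsv", sep="\t", index=False)
        truth_cn = study.depth.truth_cn or {}
        errors = {
            r.region: _round(abs(r.mean_cn - truth_cn[r.region]))
            for r in cn_df.itertuples(index=False)
            if r.region in truth_cn
        }
        summary["copy_number"] = {
            "estimates": {r.region: _round(r.mean_cn) for r in cn_df.itertuples(index=False)},
            "truth": {k: v for k, v in sorted(truth_cn.items())},
            "abs_error": errors,
        }

    sfio.write_json(summary, out / "summary.json")
    return summary
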