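"""Motif annotation and the dual-ORF anatomy of the fusion transcript.

Solo gene-A transcripts terminate at an internal polyA signal (AATAAA
within 20 bp of the 3' end); fusion splicing removes it. The fusion
transcript carries two large ORFs offset by two bases — different frames,
so no fused protein is possible — with a Kozak context (A-N-N-A-T-G-G)
spanning the fusion acceptor site. Tryptic digestion yields peptides that
tell near-identical paralogous proteins apart.
"""

from segfuse import (
    ReadBlocks, SimConfig, find_kozak, find_orfs, find_polya,
    mutually_exclusive_orfs, simulate_study, translate_orf,
    unique_peptides, validate_junctions,
)
from segfuse.simulate import SOLO_A, b_transcript, fusion_transcript

study = simulate_study(SimConfig(seed=4))
ps = study.paralog_set

solo_a = next(r for r in study.reads if r.truth_class == SOLO_A)
hit = find_polya(solo_a.id, solo_a.truth_blocks[-1][1], ps.genome, "+")
print(f"solo-A read {solo_a.id}: AATAAA at {hit.position:,}, "
      f"{hit.distance_from_end} bp from the 3' end")
jc = validate_junctions(
    ReadBlocks(solo_a.id, ps.chrom, tuple(solo_a.truth_blocks), "+"), ps.genome
)
print(f"junctions: {len(jc)}, all canonical GT/AG: {all(c.canonical for c in jc)}")

ftx = fusion_transcript(ps)
orfs = sorted(find_orfs(ftx), key=lambda o: -o.codons)[:2]
o1, o2 = sorted(orfs, key=lambda o: o.start)
print(f"ORF1: {o1.codons} codons (frame {o1.frame}); ORF2: {o2.codons} codons "
      f"(frame {o2.frame}); start offset {o2.start - o1.start} "
      f"({(o2.start - o1.start) % 3} mod 3 -> mutually exclusive: "
      f"{mutually_exclusive_orfs(orfs)[0].mutually_exclusive})")
print(f"Kozak contexts on the fusion transcript: "
      f"{[(k.position, k.context) for k in find_kozak(ftx) if k.position == o2.start]}")

pa = translate_orf(b_transcript(ps, ps.expressed_paralog),
                   max(find_orfs(b_transcript(ps, ps.expressed_paralog)), key=lambda o: o.codons))
pb = translate_orf(b_transcript(ps, "paralog_1"),
                   max(find_orfs(b_transcript(ps, "paralog_1")), key=lambda o: o.codons))
ua, ub = unique_peptides(pa, pb)
print(f"tryptic peptides unique to the expressed copy: {len(ua)} "
      f"(e.g. {ua[0] if ua else '-'})")

# ORF2 (the canonical downstream gene product) begins 13 nt upstream of
# ORF1's stop; the two-base frame offset means the fusion cannot encode a
# chimeric protein, only two independent ones.
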