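"""Build a synthetic segmental-duplication study and look at its anatomy.

The generator lays out a cluster of near-identical gene-B copies on one
chromosome; the terminal copy sits downstream of gene A, an 11-exon
partial duplicate whose promoter drives a fusion transcript spliced from
the gene-A exon-10 donor to the gene-B exon-2 acceptor.
"""

from segfuse import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
ps = study.paralog_set
m = study.model

print(f"chromosome: {len(ps.genome):,} bp, {len(ps.paralogs)} paralogs")
for p in ps.paralogs:
    tag = " <- expressed (fused) copy" if p.id == ps.expressed_paralog else ""
    print(f"  {p.id}: {p.start:,}-{p.end:,} ({len(ps.truth_variants[p.id])} variants){tag}")
print(f"gene A: {len(m.gene_a_exons)} exons, TSS at {m.gene_a_tss:,}")
print(f"merged junction: donor {m.merged_junction[0]:,} -> acceptor {m.merged_junction[1]:,}")
print(f"internal polyA site: {m.internal_polya_site:,} "
      f"(+{m.internal_polya_site - m.gene_a_exons[-1][1]} bp past the exon-11 donor)")
classes = {c: sum(r.truth_class == c for r in study.reads) for c in ("SOLO_A", "SOLO_B", "FUSION")}
print(f"reads: {classes}")
print(f"CpG calls: {len(study.methylation):,}; depth windows: {len(study.depth.windows)}")

# The variant counts per copy realise ~1% per-copy divergence (~2% pairwise),
# the high-identity regime in which paralog-specific analysis is hard.
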