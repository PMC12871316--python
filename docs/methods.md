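# Methods

This note documents the models behind `segfuse`: what the synthetic-study
generator emulates (and deliberately does not), the analysis rules and
their parameters, the numerical choices, and the limitations that follow.

## The synthetic study

The generator builds, from a seed and explicit parameters, a single
chromosome carrying `n_paralogs` (default 4) copies of a ~10.4 kb "gene
B" cassette — a 14-exon gene with canonical GT..AG introns — separated by
5.2 kb of intergenic sequence. The terminal copy is preceded by "gene A",
an 11-exon partial duplicate of an unrelated gene, so that gene A's
promoter sits directly upstream of the terminal gene-B copy. This is the
position-effect architecture the analyses target.

**Mutation model.** Each cassette copy is mutated independently with
per-base substitution probability `divergence` (default 0.01, i.e. ~2%
pairwise — the high-identity segmental-duplication regime), uniform over
the three alternative bases, no gene conversion. Functional elements are
exempt: splice dinucleotides, planted polyA hexamers, the Kozak context,
and ORF start/stop codons are never mutated, and by default proposed
substitutions that would create an in-frame stop inside the planted ORFs
are redirected to a harmless alternative (`protect_orfs=False` disables
this). The exemption mirrors the empirical observation that reading
frames in such families stay largely intact across haplotypes, and it
keeps paralog-pair protein comparisons well-defined. Locus-level indels
are out of scope (they would break the coordinate homology between copies
that assignment and classification truth-checking rely on); read-level
indels are available via `read_indel_rate` (default 0).

**Transcript architecture.** Three isoform classes:

* *solo-A*: gene-A exons 1–11, reading through the exon-11 donor to an
  internal polyadenylation site `internal_polya_offset` (default 111) bp
  downstream, with the AATAAA hexamer ending 5 nt before the 3' end;
* *fusion*: gene-A exons 1–10 spliced from the exon-10 donor to the
  gene-B exon-2 acceptor, then gene-B exons 2–14;
* *solo-B*: gene-B exons 1–14, drawn uniformly across copies.

A read is solo-A with probability `solo_a_fraction` (default 0.25);
remaining reads are fusions with probability `fusion_fraction` (default
0.5), else solo-B. Reads are the spliced sequence plus uniform
substitution errors (`read_error_rate`, default 0.005, the long-read
HiFi-like regime); homopolymer artifacts are not modelled. An optional
`single_exon_fraction` truncates reads to one exon block — the
contamination the single-exon exclusion removes.

**Planted reading frames.** The first 15 nt of gene-B exon 2 are fixed
(`CCATGGCCCCCCTAA`) so that, on the fusion transcript, ORF1
(`orf1_codons`, default 449) ends with four codons plus stop inside exon
B2 while ORF2 (`orf2_codons`, default 546) starts 2 nt into the exon —
13 nt upstream of ORF1's end, hence offset from ORF1's frame by two
bases, with its ATG completing an `A-N-N-A-T-G-G` Kozak context that
spans the fusion acceptor. Two default ORF-length conventions circulate
for this kind of locus (449 vs 479 codons for the upstream frame); the
generator parameterises the length and defaults to 449. Non-coding filler
is scrubbed of ATG so the planted ORFs are recovered with exact codon
counts; an in-frame stop guards each planted ATG against upstream
extension.

**Methylation.** CpG positions are taken from the generated sequence
(~1/16 density). Each CpG draws a methylation level from a Beta
distribution (concentration 20) whose mean depends on region: expressed
gene body 0.8, silent gene bodies 0.2, intergenic background 0.75, and a
promoter window (TSS−500 to TSS+100) at 0.1 for the expressed copy only.
Coverage is Poisson(`cpg_coverage_mean`, default 30); methylated counts
are Binomial(coverage, level). The 0.75 intergenic background represents
the broadly methylated genomic baseline; together with >5 kb of
intergenic spacing it guarantees that the upstream search window of a
silent copy never overlaps another copy's (low-methylation) gene body —
otherwise a 0.2 gene body would read as a spurious dip at the 0.25
threshold. The generator does not model read-level haplotype phasing,
partially methylated domains, or chromatin-accessibility footprints, so
passing tests demonstrate the detector's behaviour under clean
region-wise regimes, not its robustness to those confounders.

**Depth.** Windowed WGS depth is Poisson(`depth_mean × CN/2`) per 1 kb
window, `windows_per_region` (default 20) windows per configured region,
plus two CN=2 control regions. No GC bias is simulated (the estimator
exposes no correction, only the control normalisation).

## Analysis rules and parameters

* **Scoring** (`align`): Smith–Waterman with affine gaps; match +1,
  mismatch −2, a length-k gap costs 4 + 2k. The convention that the gap
  open charge includes the first gap base is a definition choice; the
  exhaustive-oracle and cross-aligner tests pin it. Bulk assignment uses
  a banded kernel around a k-mer-seeded diagonal (k=21, stride 7, band
  64): exact whenever the optimal path stays in the corridor, which holds
  by construction for substitution-only differences; the full dynamic
  program is the fallback (no seed) and the reference implementation.
* **Assignment** (`assign`): strict best-over-second-best; ties of any
  multiplicity are AMBIGUOUS; a single candidate has second score −∞ and
  is assigned. All non-primary candidate scores are eligible as the
  runner-up. External fractional scores are floored to integers.
* **Classification** (`classify`): fusion requires ≥`min_exon_overlap`
  (default 10) bp of exon overlap on *both* genes — robust to alignment
  jitter; `strict_junction` additionally requires the exact donor →
  acceptor splice. Single-exon reads are excluded before anything else;
  antisense reads are UNASSIGNED. Whether unassigned intron-only reads
  should enter fusion-fraction denominators is genuinely open; here they
  do not (the denominator is fusion + solo-B).
* **Motifs** (`motifs`): the polyA scan requires the hexamer fully inside
  the 20 bp window ending at the aligned 3' end, on the transcribed
  strand, reporting the occurrence closest to the end; the window is
  measured in genomic coordinates of the alignment end. Only AATAAA by
  default; ATTAAA behind `include_variants`. Junction dinucleotides
  follow the GT-donor/AG-acceptor convention. The Kozak pattern is
  matched literally (A at −3, G at +4); no strength scoring.
* **Methylation** (`methylation`): the coverage filter keeps sites with
  ≥6 reads, exactly. The rolling mean is centred, over 15 consecutive
  CpG *sites* (index space, not bp), with shrunken windows at the edges
  so track length is preserved; a trailing window is the other
  defensible convention and centred was chosen. Dip calling: ≥5
  consecutive smoothed values < 0.25 within 5 kb upstream of the TSS
  (strand-aware); the thresholds are not canonical constants but chosen
  to separate a ~0.1 promoter dip from a methylated background with
  margin, and all three are parameters. The flank level is the median
  smoothed value in the window outside the dip.
* **Coding** (`coding`): ORFs are reported per stop codon (first ATG
  after the previous in-frame stop), stop-terminated only, ≥50 codons by
  default; only the transcript's sense strand is scanned. The variant
  classifier gives splice-site hits precedence, calls frameshift on
  indels with length change ≠ 0 mod 3, and otherwise compares the mutant
  translation against the reference with the expected stop index shifted
  by in-frame indel length — an earlier stop is stop_gained, a removed
  stop is stop_lost, in-frame indels classify as missense-level.
  Pathogenicity scoring (trained external resources) is deliberately
  replaced by this rule-based classifier. Trypsin cleaves after K/R
  except before P, zero missed cleavages by default (`missed_cleavages`
  configurable); the named Expasy rule's extra W-K-P/M-R-P cleavages are
  out of scope. Unique peptides require length ≥7 (a practical
  detectability floor) and absence from the partner's (and optional
  background) digest.
* **Copy number** (`cn`): region average of `2 × query/control` window
  means; scale-invariant; window size 1 kb by default (not a canonical
  value). Rank-order recovery across the 3–39 polymorphic range uses
  1500-window regions, since adjacent integer states at 30× need that
  much averaging to separate by >5σ.

## Determinism and numerics

All generators draw from `numpy` Generator substreams keyed by
`(seed, stage)`, so stages are independently reproducible and identical
configurations give byte-identical outputs (JSON is written with sorted
keys; summary floats are rounded to 6 decimals). Smoothing uses
cumulative sums (agreement with a direct mean to <1e−12 is under test).
Alignment scores are int64 throughout; the banded kernel's corridor
boundary cells reset to the local-alignment floor of 0, which can only
underestimate paths that leave the corridor.

## Problem sizes used in tests and the reproduction script

Assignment: 500 reads × 10 seeds at 1% divergence, 0.5% error (and one
zero-divergence tie check). Mixture recovery: fractions 0.1/0.5/0.9,
20 seeds × 400 reads. Dip calling: 100 independent loci. ORF oracle:
1000 random 2 kb sequences. Digest: 1000 random proteins. Copy number:
CN ∈ {2,3,6,10} × 10 seeds at 30×, plus one 3–39 sweep. A full
reproduction run completes in about a minute on one core.

## Known limitations

The generator's clean region-wise regimes (uniform error, no indels, no
GC or mappability structure, plus-strand genes only, exact truth blocks
in place of a spliced aligner's output) mean the test suite validates the
analysis rules and their statistical recovery, not robustness to real
alignment artifacts. Strand-aware code paths exist and are tested on
constructed cases, but the simulator never exercises them end-to-end.
Real-data use is supported at the interfaces: SAM `AS` scores for
assignment, BED12 blocks for classification and motifs, bedMethyl-style
tables for methylation, and precomputed depth windows for copy number.
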