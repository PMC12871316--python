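"""Generator contracts: determinism, divergence statistics, planted-motif
integrity, truth completeness, and the configured coverage/depth models."""

import numpy as np
import pytest

from segfuse import (
    FUSION,
    SOLO_A,
    SOLO_B,
    CpGCall,
    InputError,
    ParameterError,
    SimConfig,
    fusion_transcript,
    generate_paralog_set,
    simulate_depth,
    simulate_methylation,
    simulate_study,
    simulate_transcripts,
    solo_a_transcript,
)
from segfuse.simulate import write_study


def test_identical_configs_are_byte_identical(tmp_path):
    a = simulate_study(SimConfig(seed=3, n_reads=50))
    b = simulate_study(SimConfig(seed=3, n_reads=50))
    write_study(a, tmp_path / "a")
    write_study(b, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_zero_divergence_yields_identical_copies():
    ps = generate_paralog_set(SimConfig(seed=1, divergence=0.0, n_paralogs=3))
    seqs = {p.sequence for p in ps.paralogs}
    assert len(seqs) == 1
    assert all(not v for v in ps.truth_variants.values())


def test_pairwise_divergence_matches_binomial_expectation():
    """Two copies mutated independently at rate p differ at ~2p(1-p) of
    sites; the observed count must sit within 3 sigma of that binomial."""
    cfg = SimConfig(seed=1, divergence=0.01, n_paralogs=2)
    ps = generate_paralog_set(cfg)
    a = np.frombuffer(ps.paralogs[0].sequence.encode(), np.uint8)
    b = np.frombuffer(ps.paralogs[1].sequence.encode(), np.uint8)
    L = a.size
    p_pair = 2 * 0.01 * 0.99 + 0.01 * 0.01 * (2 / 3)  # same-site different alts
    mean = L * p_pair
    sigma = np.sqrt(L * p_pair * (1 - p_pair))
    assert abs(int((a != b).sum()) - mean) < 3 * sigma


def test_divergence_outside_unit_interval_rejected():
    with pytest.raises(ParameterError):
        SimConfig(divergence=1.5)
    with pytest.raises(ParameterError):
        SimConfig(n_paralogs=0)


def test_truth_variants_recorded_and_applied():
    cfg = SimConfig(seed=9, n_paralogs=2, divergence=0.01)
    ps = generate_paralog_set(cfg)
    anc = ps.ancestral_cassette
    for pid, variants in ps.truth_variants.items():
        seq = next(p.sequence for p in ps.paralogs if p.id == pid)
        assert len(variants) > 0
        for pos, ref, alt in variants:
            assert anc[pos] == ref and seq[pos] == alt


def test_solo_a_reads_carry_polya_hexamer_in_final_20nt(default_study):
    solo_a = [r for r in default_study.reads if r.truth_class == SOLO_A]
    assert solo_a, "study should contain solo-A reads"
    ps = default_study.paralog_set
    for r in solo_a:
        assert r.truth_blocks[-1][1] == ps.fusion_model.internal_polya_site
        spliced = "".join(ps.genome[s:e] for s, e in r.truth_blocks)
        assert "AATAAA" in spliced[-20:]


def test_all_planted_junctions_are_gt_ag(default_study):
    g = default_study.paralog_set.genome
    for r in default_study.reads:
        for (_, e1), (s2, _) in zip(r.truth_blocks, r.truth_blocks[1:]):
            assert g[e1 : e1 + 2] == "GT" and g[s2 - 2 : s2] == "AG"


def test_degenerate_mixture_all_fusion():
    cfg = SimConfig(seed=2, fusion_fraction=1.0, solo_a_fraction=0.0, n_reads=80)
    ps = generate_paralog_set(cfg)
    reads = simulate_transcripts(ps, ps.fusion_model, cfg)
    model = ps.fusion_model
    for r in reads:
        assert r.truth_class == FUSION
        hits_a = any(b[0] < model.gene_a_exons[-1][1] for b in r.truth_blocks)
        hits_b = any(b[1] > model.gene_b_exons[0][1] for b in r.truth_blocks)
        assert hits_a and hits_b


def test_fusion_count_within_binomial_ci():
    cfg = SimConfig(seed=7, fusion_fraction=0.5, solo_a_fraction=0.0, n_reads=400)
    ps = generate_paralog_set(cfg)
    reads = simulate_transcripts(ps, ps.fusion_model, cfg)
    n_fus = sum(r.truth_class == FUSION for r in reads)
    assert abs(n_fus - 200) < 1.96 * np.sqrt(400 * 0.25)


def test_reads_multi_exon_unless_contamination_configured():
    cfg = SimConfig(seed=4, n_reads=100)
    ps = generate_paralog_set(cfg)
    assert all(len(r.truth_blocks) > 1 for r in simulate_transcripts(ps, ps.fusion_model, cfg))
    cfg2 = SimConfig(seed=4, n_reads=200, single_exon_fraction=0.3)
    reads = simulate_transcripts(ps, ps.fusion_model, cfg2)
    n_single = sum(len(r.truth_blocks) == 1 for r in reads)
    assert 30 < n_single < 90


def test_read_sequences_match_spliced_blocks_at_zero_error():
    cfg = SimConfig(seed=5, read_error_rate=0.0, n_reads=40)
    ps = generate_paralog_set(cfg)
    for r in simulate_transcripts(ps, ps.fusion_model, cfg):
        assert r.sequence == "".join(ps.genome[s:e] for s, e in r.truth_blocks)


def test_zero_cpg_coverage_gives_empty_calls():
    cfg = SimConfig(seed=1, cpg_coverage_mean=0.0)
    ps = generate_paralog_set(cfg)
    assert simulate_methylation(ps, ps.expressed_paralog, cfg) == []


def test_methylation_rejects_unknown_paralog():
    cfg = SimConfig(seed=1)
    ps = generate_paralog_set(cfg)
    with pytest.raises(InputError):
        simulate_methylation(ps, "nope", cfg)


def test_cpgcall_invariant():
    with pytest.raises(InputError):
        CpGCall(10, 5, 6)


def test_expressed_vs_silent_gene_body_contrast(default_study):
    """The configured Beta means (0.8 vs 0.2) must separate expressed and
    silent copies by more than 0.3 on raw per-CpG fractions."""
    ps = default_study.paralog_set
    calls = default_study.methylation
    frac = {c.position: c.methylated / c.coverage for c in calls if c.coverage >= 6}
    pos = np.array(sorted(frac))
    vals = np.array([frac[p] for p in pos])

    def body_mean(pid):
        lo, hi = ps.tss_by_paralog[pid], ps.tts_by_paralog[pid]
        sel = (pos >= lo) & (pos < hi)
        return vals[sel].mean()

    expressed = body_mean(ps.expressed_paralog)
    silents = [body_mean(p) for p in ps.paralog_ids() if p != ps.expressed_paralog]
    assert expressed - max(silents) > 0.3


def test_depth_zero_mean_gives_zero_track():
    cfg = SimConfig(seed=1, depth_mean=0.0)
    ps = generate_paralog_set(cfg)
    assert (simulate_depth(ps, cfg).windows["count"] == 0).all()


def test_depth_requires_cn2_control():
    cfg = SimConfig(seed=1, copy_numbers={"q": 6, "control_1": 4})
    ps = generate_paralog_set(cfg)
    with pytest.raises(ParameterError):
        simulate_depth(ps, cfg)


def test_depth_scales_with_copy_number():
    cfg = SimConfig(seed=3, depth_mean=30.0, copy_numbers={"q": 6, "control_1": 2},
                    windows_per_region=50)
    ps = generate_paralog_set(cfg)
    track = simulate_depth(ps, cfg)
    q = track.windows.query("region == 'q'")["count"].mean()
    c = track.windows.query("region == 'control_1'")["count"].mean()
    lam_q, n = 90.0, 50
    sigma_ratio = (lam_q / 30.0) * np.sqrt(1 / (lam_q * n) + 1 / (30.0 * n))
    assert abs(q / c - 3.0) < 3 * sigma_ratio


def test_fusion_transcript_is_a_exons_plus_b_exons(small_study):
    ps = small_study.paralog_set
    ft = fusion_transcript(ps)
    m = ps.fusion_model
    lens = sum(e - s for s, e in m.gene_a_exons[:10]) + sum(
        e - s for s, e in m.gene_b_exons[1:]
    )
    assert len(ft) == lens
    assert solo_a_transcript(ps).endswith(ps.genome[
        m.internal_polya_site - 20 : m.internal_polya_site])
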