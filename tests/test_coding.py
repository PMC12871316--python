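"""ORF discovery (against a brute-force enumerator), overlapping-frame
logic, variant consequences, and tryptic digestion (against pyteomics)."""

import numpy as np
import pytest

from segfuse import (
    InputError,
    OrfRecord,
    TranscriptModel,
    classify_variant,
    find_orfs,
    fusion_transcript,
    mutually_exclusive_orfs,
    translate_orf,
    tryptic_digest,
    unique_peptides,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_orfs(seq, min_codons):
    """Independent enumeration: every (ATG, next in-frame stop) pair,
    keeping per stop the earliest ATG after the previous in-frame stop."""
    out = []
    for frame in range(3):
        codon_pos = list(range(frame, len(seq) - 2, 3))
        stops = [i for i in codon_pos if seq[i : i + 3] in STOPS]
        atgs = [i for i in codon_pos if seq[i : i + 3] == "ATG"]
        prev = frame - 3
        for stop in stops:
            cands = [a for a in atgs if prev < a < stop]
            if cands:
                start = min(cands)
                codons = (stop + 3 - start) // 3 - 1
                if codons >= min_codons:
                    out.append((start, stop + 3, codons))
            prev = stop
    return sorted(out)


def test_minimal_orf_hand_example():
    orfs = find_orfs("ATGAAATAG", min_codons=1)
    assert len(orfs) == 1
    o = orfs[0]
    assert (o.start, o.end, o.codons, o.frame) == (0, 9, 2, 0)


def test_no_atg_means_no_orfs():
    assert find_orfs("CCCCCCTAACCC", min_codons=1) == []


def test_invalid_symbols_rejected():
    with pytest.raises(InputError):
        find_orfs("ATGNNNTAG")


def test_find_orfs_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(0)
    for _ in range(60):
        seq = "".join(rng.choice(list("ACGT"), 800))
        for min_codons in (1, 10, 30):
            ours = [(o.start, o.end, o.codons) for o in find_orfs(seq, min_codons)]
            assert sorted(ours) == brute_orfs(seq, min_codons)


def test_overlap_offsets_decide_frame_exclusivity():
    a = OrfRecord(100, 400, 1, 99)
    b = OrfRecord(102, 300, 0, 65)
    c = OrfRecord(103, 301, 1, 65)
    pairs = mutually_exclusive_orfs([a, b])
    assert pairs[0].base_offset == 2 and pairs[0].mutually_exclusive
    pairs = mutually_exclusive_orfs([a, c])
    assert pairs[0].base_offset == 3 and pairs[0].same_frame
    # a 13-base offset also lands out of frame
    d = OrfRecord(87, 250, 0, 53)
    pairs = mutually_exclusive_orfs([d, a])
    assert pairs[0].base_offset == 13 and pairs[0].mutually_exclusive


def test_non_overlapping_orfs_not_paired():
    a = OrfRecord(0, 90, 0, 29)
    b = OrfRecord(90, 180, 0, 29)
    assert mutually_exclusive_orfs([a, b]) == []


def test_synthetic_fusion_transcript_carries_both_planted_orfs(small_study):
    """The fused transcript must show the two planted reading frames with
    exact codon counts, overlapping out of frame (offset 2 mod 3)."""
    ftx = fusion_transcript(small_study.paralog_set)
    orfs = find_orfs(ftx)
    by_codons = {o.codons: o for o in orfs}
    cfg = small_study.config
    assert cfg.orf1_codons in by_codons and cfg.orf2_codons in by_codons
    o1, o2 = by_codons[cfg.orf1_codons], by_codons[cfg.orf2_codons]
    assert o2.start - o1.start == 1337  # ORF2 begins 13 nt upstream of ORF1's end
    assert o1.end - o2.start == 13
    pair = [
        p
        for p in mutually_exclusive_orfs(orfs)
        if {p.orf_i, p.orf_j} == {o1, o2}
    ]
    assert pair and pair[0].mutually_exclusive and pair[0].base_offset % 3 == 2


# ---------------------------------------------------------------------------
# variant consequences


@pytest.fixture()
def toy_model():
    # two exons, intron with GT..AG; ORF spans the junction
    exon1 = "ATGCAGAAA"          # M Q K
    intron = "GT" + "C" * 8 + "AG"
    exon2 = "GGGTTTTAA"          # G F *
    genome = "CCC" + exon1 + intron + exon2 + "CCC"
    blocks = [(3, 12), (24, 33)]
    orf = OrfRecord(0, 18, 0, 5)
    return TranscriptModel(genome, blocks, orf)


def test_stop_gained_from_gln_codon(toy_model):
    # CAG -> TAG at the Gln codon (genomic 6 is the C of CAG)
    c = classify_variant(toy_model, (6, "C", "T"))
    assert c.consequence == "stop_gained"
    assert c.new_stop_position == 3


def test_splice_site_dinucleotide_hit(toy_model):
    c = classify_variant(toy_model, (12, "G", "A"))  # GT -> AT donor
    assert c.consequence == "splice_site"


def test_inframe_deletion_is_not_frameshift(toy_model):
    c = classify_variant(toy_model, (6, "CAGA", "A"))
    assert c.consequence == "missense"


def test_frameshift_indel(toy_model):
    c = classify_variant(toy_model, (6, "CA", "C"))
    assert c.consequence == "frameshift"


def test_missense_synonymous_and_stop_lost(toy_model):
    assert classify_variant(toy_model, (7, "A", "T")).consequence == "missense"
    # AAA -> AAG, both Lys
    assert classify_variant(toy_model, (11, "A", "G")).consequence == "synonymous"
    # TAA stop -> CAA Gln
    assert classify_variant(toy_model, (30, "T", "C")).consequence == "stop_lost"


def test_ref_mismatch_rejected(toy_model):
    with pytest.raises(InputError):
        classify_variant(toy_model, (6, "G", "A"))


# ---------------------------------------------------------------------------
# tryptic digest


def test_digest_hand_examples():
    assert [p for p, _, _ in tryptic_digest("MKRPK").peptides] == ["MK", "RPK"]
    assert [p for p, _, _ in tryptic_digest("AAAA").peptides] == ["AAAA"]


def test_digest_reconstruction_identity():
    rng = np.random.default_rng(1)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(50):
        prot = "".join(rng.choice(aas, int(rng.integers(1, 200))))
        peps = tryptic_digest(prot).peptides
        assert "".join(p for p, _, _ in peps) == prot
        for p, s, e in peps:
            assert prot[s:e] == p


def test_digest_agrees_with_pyteomics():
    """Cross-check against pyteomics' cleavage engine under the plain
    K/R-not-before-P rule (Expasy's named trypsin rule additionally cleaves
    at W-K-P / M-R-P, which is out of scope here)."""
    parser = pytest.importorskip("pyteomics.parser")
    rng = np.random.default_rng(2)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    rule = r"(?<=[KR])(?!P)"
    for _ in range(25):
        prot = "".join(rng.choice(aas, 120))
        ours = sorted({p for p, _, _ in tryptic_digest(prot).peptides})
        theirs = sorted(parser.cleave(prot, rule, missed_cleavages=0))
        assert ours == theirs


def test_invalid_residue_rejected():
    with pytest.raises(InputError):
        tryptic_digest("MKXK")


def test_missed_cleavages_add_spanning_peptides():
    peps = {p for p, _, _ in tryptic_digest("MKAAARGGG", missed_cleavages=1).peptides}
    assert {"MK", "AAAR", "GGG", "MKAAAR", "AAARGGG"} <= peps


def test_unique_peptides_identity_and_single_substitution():
    prot = "MAAAKGGGGRDDDDK"
    assert unique_peptides(prot, prot) == ([], [])
    mutated = prot.replace("GGGGR", "GGGSR")
    ua, ub = unique_peptides(prot, mutated, min_length=4)
    assert ua == ["GGGGR"] and ub == ["GGGSR"]


def test_unique_peptides_match_brute_force_on_paralog_pair(small_study):
    """Near-identical paralogous proteins: unique sets equal the brute
    digest set difference."""
    ps = small_study.paralog_set
    from segfuse import b_transcript

    prots = []
    for pid in (ps.expressed_paralog, ps.paralog_ids()[0]):
        tx = b_transcript(ps, pid)
        orf = max(find_orfs(tx), key=lambda o: o.codons)
        prots.append(translate_orf(tx, orf))
    pa, pb = prots
    ua, ub = unique_peptides(pa, pb)
    da = {p for p, _, _ in tryptic_digest(pa).peptides}
    db = {p for p, _, _ in tryptic_digest(pb).peptides}
    assert set(ua) == {p for p in da - db if len(p) >= 7}
    assert set(ub) == {p for p in db - da if len(p) >= 7}
    assert pa != pb and (ua or ub)


def test_background_filter_removes_shared_peptides():
    a = "MAAAKGGGGR"
    b = "MAAAKCCCCR"
    ua, ub = unique_peptides(a, b, min_length=4, background=["GGGGR"])
    assert ua == [] and ub == ["CCCCR"]
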