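"""Transcript classification: the dual-gene overlap rule, single-exon
exclusion, class partition, and the count/fraction/TPM arithmetic."""

import numpy as np
import pandas as pd
import pytest

from segfuse import (
    EXCLUDED,
    FUSION,
    SOLO_A,
    SOLO_B,
    UNASSIGNED,
    ClassCounts,
    InputError,
    ParameterError,
    ReadBlocks,
    classify_read,
    count_classes,
    fusion_fraction,
    tpm_normalize,
)
from segfuse.simulate import classification_model


@pytest.fixture(scope="module")
def model(small_study):
    return classification_model(small_study.paralog_set)


def _rb(blocks, strand="+", chrom="chrSim"):
    return ReadBlocks("r", chrom, tuple(blocks), strand)


def test_fusion_requires_overlap_on_both_genes(model):
    a_ex = model.gene_a_exons
    b_ex = model.gene_b_exons
    fusion = _rb([a_ex[9], b_ex[-1]])
    assert classify_read(fusion, model) == FUSION


def test_single_block_read_excluded(model):
    b_ex = model.gene_b_exons
    assert classify_read(_rb([b_ex[2]]), model) == EXCLUDED


def test_solo_classes_and_unassigned(model):
    a_ex = model.gene_a_exons
    b_ex = model.gene_b_exons
    assert classify_read(_rb([a_ex[0], a_ex[1]]), model) == SOLO_A
    assert classify_read(_rb([b_ex[0], b_ex[1]]), model) == SOLO_B
    # intronic-only blocks touch no exon
    gap1 = (a_ex[0][1] + 50, a_ex[0][1] + 80)
    gap2 = (a_ex[1][1] + 50, a_ex[1][1] + 80)
    assert classify_read(_rb([gap1, gap2]), model) == UNASSIGNED


def test_antisense_reads_unassigned(model):
    a_ex = model.gene_a_exons
    assert classify_read(_rb([a_ex[0], a_ex[1]], strand="-"), model) == UNASSIGNED


def test_min_overlap_threshold(model):
    a_ex = model.gene_a_exons
    b_ex = model.gene_b_exons
    sliver = (b_ex[-1][0], b_ex[-1][0] + 5)  # 5 bp < default 10
    read = _rb([a_ex[0], a_ex[1], sliver])
    assert classify_read(read, model) == SOLO_A
    assert classify_read(read, model, min_exon_overlap=5) == FUSION


def test_strict_junction_mode(small_study, model):
    m = small_study.paralog_set.fusion_model
    donor, acceptor = m.merged_junction
    a_ex = model.gene_a_exons
    spliced = _rb([a_ex[8], (a_ex[9][0], donor), (acceptor, acceptor + 50)])
    jittered = _rb([a_ex[8], (a_ex[9][0], donor - 3), (acceptor + 3, acceptor + 50)])
    assert classify_read(spliced, model, strict_junction=True) == FUSION
    assert classify_read(jittered, model, strict_junction=True) == UNASSIGNED
    assert classify_read(jittered, model) == FUSION


def test_chrom_mismatch_rejected(model):
    with pytest.raises(InputError):
        classify_read(_rb([(0, 50), (100, 150)], chrom="other"), model)


def test_every_read_lands_in_exactly_one_class(default_study):
    """Partition invariant plus exact truth recovery at zero read error
    (classification uses truth blocks, so labels must match)."""
    model = classification_model(default_study.paralog_set)
    classes = {}
    for r in default_study.reads:
        rb = ReadBlocks(r.id, "chrSim", tuple(r.truth_blocks), r.strand)
        classes[r.id] = classify_read(rb, model)
    assert set(classes.values()) <= {SOLO_A, SOLO_B, FUSION}
    for r in default_study.reads:
        assert classes[r.id] == r.truth_class
    counts = count_classes(classes.values())
    assert (
        counts.solo_a + counts.solo_b + counts.fusion
        + counts.excluded_single_exon + counts.unassigned
        == len(default_study.reads)
    )


def test_count_classes_empty_and_unknown():
    c = count_classes([])
    assert (c.solo_a, c.solo_b, c.fusion, c.excluded_single_exon, c.unassigned) == (0,) * 5
    with pytest.raises(InputError):
        count_classes(["NOT_A_CLASS"])


def test_fusion_fraction_paper_style_tally():
    """116 fusion over 206 gene-B reads is a 56% fusion fraction."""
    c = ClassCounts(solo_a=10, solo_b=90, fusion=116)
    assert fusion_fraction(c) == pytest.approx(116 / 206)
    assert fusion_fraction(ClassCounts(fusion=0, solo_b=5)) == 0.0
    assert fusion_fraction(ClassCounts()) is None


def test_tpm_columns_sum_to_one_million():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.integers(1, 1000, size=(30, 4)),
                      columns=[f"lib{i}" for i in range(4)])
    tpm = tpm_normalize(df)
    assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6)


def test_tpm_simple_cases_and_zero_total():
    df = pd.DataFrame({"lib": {"g1": 1, "g2": 1}})
    assert (tpm_normalize(df)["lib"] == 500000.0).all()
    assert tpm_normalize(pd.DataFrame({"lib": {"g1": 3}}))["lib"]["g1"] == 1e6
    with pytest.raises(ParameterError):
        tpm_normalize(pd.DataFrame({"lib": {"g1": 0}}))
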