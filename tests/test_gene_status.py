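"""Variant filters, gene CN/SV annotation, BAL/MAL/Intact integration."""
import itertools

import pytest

from tdpscan.model import (
    CopyNumberSegment,
    GenomicInterval,
    SVBreakpoint,
    SVEvent,
    VariantCall,
)
from tdpscan.gene_status import (
    annotate_gene_cn,
    annotate_gene_sv,
    call_allelic_status,
    filter_indels,
    filter_snvs,
    filter_variants,
)

GENE = GenomicInterval("chr1", 10_000_000, 10_100_000, "G", role="gene")


def snv(caller_count=3, clnsig="pathogenic", func="exonic", **kw):
    return VariantCall("chr1", 10_050_000, "C", "T", "snv",
                       caller_count=caller_count, clnsig=clnsig, func=func,
                       alt_reads=30, ref_reads=60, gene="G", **kw)


def indel(alt=12, ref=40, clnsig="pathogenic", func="exonic"):
    return VariantCall("chr1", 10_050_000, "CT", "C", "indel", caller_count=1,
                       clnsig=clnsig, func=func, alt_reads=alt, ref_reads=ref,
                       gene="G")


@pytest.mark.parametrize(
    "call,kept",
    [
        (snv(), True),
        (snv(caller_count=1), False),
        (snv(clnsig="benign"), False),
        (snv(clnsig="likely_benign"), False),
        (snv(func="intronic"), False),
        (snv(func="splicing"), True),
    ],
)
def test_snv_filter(call, kept):
    assert (filter_snvs([call]) == [call]) is kept


def test_snv_missing_annotation_excluded_with_warning():
    with pytest.warns(UserWarning, match="missing annotations"):
        assert filter_snvs([snv(clnsig=".")]) == []


@pytest.mark.parametrize(
    "alt,ref,clnsig,kept",
    [
        (12, 40, "pathogenic", True),
        (4, 50, "pathogenic", False),   # alt < 5 (and vaf 0.074 <= 0.1)
        (5, 9, "pathogenic", False),    # ref < 10
        (5, 10, "pathogenic", True),    # boundary pass: vaf 1/3 > 0.1
        (5, 45, "pathogenic", False),   # vaf exactly 0.1: strict >
        (12, 40, "benign", False),
    ],
)
def test_indel_filter(alt, ref, clnsig, kept):
    assert (filter_indels([indel(alt, ref, clnsig)]) == [indel(alt, ref, clnsig)]) is kept


def test_filters_idempotent_and_order_independent():
    calls = [snv(), snv(caller_count=1), indel(), indel(4, 50)]
    once = filter_variants(calls)
    assert filter_variants(once) == once
    assert set(map(id, filter_variants(calls[::-1]))) == set(map(id, once))


# ---------------------------------------------------------------------------
# copy-number annotation


def seg(total, minor, cf=1.0, start=9_000_000, end=11_000_000):
    return CopyNumberSegment("chr1", start, end, total, minor, cf)


@pytest.mark.parametrize(
    "ploidy,total,minor,category,norm",
    [
        (2.0, 6, 1, "amplification", 3.0),
        (4.2, 6, 1, "gain", 1.5),          # ploidy rounds to 4; boundary inclusive
        (2.0, 0, 0, "homozygous_deletion", 0.0),
        (2.0, 2, 0, "copy_neutral_LOH", 1.0),
        (2.0, 1, 0, "deletion_LOH", 0.5),
        (2.0, 2, 1, "neutral", 1.0),
        (2.0, 3, 1, "gain", 1.5),
        (2.0, 5, 2, "amplification", 2.5),  # boundary inclusive
        (2.0, 1, 1, "neutral", 0.5),        # sub-ploidy without LOH
    ],
)
def test_cn_categories(ploidy, total, minor, category, norm):
    cat, got_norm, _ = annotate_gene_cn(GENE, [seg(total, minor)], ploidy)
    assert cat == category
    assert got_norm == pytest.approx(norm)


def test_x_linked_normalization():
    gene_x = GenomicInterval("chrX", 10_000_000, 10_100_000, "GX")
    s = CopyNumberSegment("chrX", 9_000_000, 11_000_000, 2, 0)
    cat, norm, _ = annotate_gene_cn(gene_x, [s], 2.0, sex_chrom=True)
    assert norm == pytest.approx(2.0)
    assert cat == "gain"


def test_subclonal_segment_excluded_unless_neutral_or_high_cn():
    # subclonal loss is ignored; gene falls back to the clonal segment
    subclonal_loss = seg(1, 0, cf=0.5, start=9_500_000, end=10_500_000)
    clonal = seg(2, 1, cf=1.0)
    cat, _, _ = annotate_gene_cn(GENE, [clonal, subclonal_loss], 2.0)
    assert cat == "neutral"
    # subclonal copy-neutral and subclonal high-CN survive the filter
    cat, _, _ = annotate_gene_cn(GENE, [seg(2, 0, cf=0.5)], 2.0)
    assert cat == "copy_neutral_LOH"
    cat, _, _ = annotate_gene_cn(GENE, [seg(6, 1, cf=0.5)], 2.0)
    assert cat == "amplification"
    # subclonal-only loss -> no surviving segment
    cat, norm, _ = annotate_gene_cn(GENE, [seg(1, 0, cf=0.5)], 2.0)
    assert cat is None and norm is None


def test_largest_overlap_segment_wins():
    small = seg(6, 1, start=10_000_000, end=10_010_000)   # 10 kb of gene
    large = seg(2, 1, start=10_010_001, end=11_000_000)   # 90 kb of gene
    cat, _, _ = annotate_gene_cn(GENE, [small, large], 2.0)
    assert cat == "neutral"


# ---------------------------------------------------------------------------
# SV annotation


def sv(pos1, o1, pos2, o2, sv_type, chrom2="chr1"):
    return SVEvent(SVBreakpoint("chr1", pos1, o1),
                   SVBreakpoint(chrom2, pos2, o2), sv_type=sv_type)


def test_sv_transect_precedence():
    deletion = sv(10_050_000, "+", 13_000_000, "-", "deletion")
    assert annotate_gene_sv(GENE, [deletion]) == "transect"


def test_sv_flank_short_event():
    td = sv(9_500_000, "-", 9_900_000, "+", "tandem_duplication")
    assert annotate_gene_sv(GENE, [td]) == "flank"
    far = sv(8_000_000, "-", 8_500_000, "+", "tandem_duplication")
    assert annotate_gene_sv(GENE, [far]) == "none"


def test_translocation_direction_matters():
    toward = sv(9_500_000, "+", 5_000_000, "-", "translocation", chrom2="chr9")
    away = sv(9_500_000, "-", 5_000_000, "-", "translocation", chrom2="chr9")
    assert annotate_gene_sv(GENE, [toward]) == "flank"
    assert annotate_gene_sv(GENE, [away]) == "none"
    # downstream flank, pointing back toward the gene
    toward3p = sv(10_600_000, "-", 5_000_000, "-", "translocation", chrom2="chr9")
    assert annotate_gene_sv(GENE, [toward3p]) == "flank"


def test_long_balanced_event_acts_translocation_like():
    long_bal = sv(9_500_000, "+", 25_000_000, "-", "balanced_intra")
    assert annotate_gene_sv(GENE, [long_bal]) == "flank"
    short_bal = sv(9_500_000, "+", 9_700_000, "-", "balanced_intra")
    assert annotate_gene_sv(GENE, [short_bal]) == "none"


# ---------------------------------------------------------------------------
# allelic-status integration


CN_STATES = {
    "none": ("neutral", 1.0, False),
    "hemizygous_LOH": ("deletion_LOH", 0.5, True),
    "cn_LOH": ("copy_neutral_LOH", 1.0, True),
    "hom_del": ("homozygous_deletion", 0.0, True),
}


def expected_status(n_muts, cn_state, sv_transect):
    """Independent enumeration oracle for the event-counting rules."""
    if cn_state == "hom_del":
        return "BAL"
    events = n_muts + (cn_state in ("hemizygous_LOH", "cn_LOH")) + sv_transect
    return "BAL" if events >= 2 else ("MAL" if events == 1 else "Intact")


def test_allelic_status_exhaustive_truth_table():
    for n_muts, cn_state, transect in itertools.product(
        (0, 1, 2), CN_STATES, (False, True)
    ):
        muts = [snv() for _ in range(n_muts)]
        got = call_allelic_status(
            GENE, muts, CN_STATES[cn_state], "transect" if transect else "none"
        )
        assert got.status == expected_status(n_muts, cn_state, transect), (
            n_muts, cn_state, transect,
        )


def test_sv_transect_config_switch():
    got = call_allelic_status(GENE, [snv()], CN_STATES["none"], "transect",
                              count_sv_transect=False)
    assert got.status == "MAL"
    got = call_allelic_status(GENE, [snv()], CN_STATES["none"], "transect")
    assert got.status == "BAL"


def test_hom_del_reason_reported_first():
    got = call_allelic_status(GENE, [snv(), snv()], CN_STATES["hom_del"], "none")
    assert got.status == "BAL"
    assert got.reason == "homozygous_deletion"
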