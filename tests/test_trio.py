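"""Informative-SNP selection, expressed-allele classification, aggregation."""

import pytest

from triomae import fixtures
from triomae.filters import AnnotatedSite, FilterConfig
from triomae.io import GeneAnnotation, SampleCall, VariantSite
from triomae.trio import (
    BIALLELIC,
    CONFLICTING,
    InformativeSNP,
    MAECall,
    MATERNAL,
    MissingAdError,
    MixedTissueError,
    NOT_CALLABLE,
    PATERNAL,
    SampleExpressionStatus,
    aggregate_gene,
    aggregate_tissue,
    classify_expressed_allele,
    find_informative_snps,
    summarize_mae,
)

CFG = FilterConfig()
GENE = GeneAnnotation("G1", "SYM1", "missense")


def trio_site(sire_gt, dam_gt, off_gt=None, pos=100, gq=99, dp=40):
    calls = {
        "sire": SampleCall(sire_gt, gq, dp),
        "dam": SampleCall(dam_gt, gq, dp),
    }
    if off_gt is not None:
        calls["offspring"] = SampleCall(off_gt, gq, dp)
    site = VariantSite(chrom="1", pos=pos, ref="A", alt="G", calls=calls)
    return AnnotatedSite(site=site, gene=GENE)


def test_opposite_homozygotes_are_informative():
    snps = find_informative_snps([trio_site(("A", "A"), ("G", "G"))], "sire", "dam", CFG)
    assert len(snps) == 1
    assert snps[0].paternal_allele == "A"
    assert snps[0].maternal_allele == "G"


@pytest.mark.parametrize(
    "sire_gt,dam_gt",
    [
        (("A", "A"), ("A", "A")),  # same homozygote: not opposite
        (("A", "G"), ("G", "G")),  # heterozygous parent
        (("A", "G"), ("A", "G")),
    ],
)
def test_non_opposite_parents_excluded(sire_gt, dam_gt):
    assert find_informative_snps([trio_site(sire_gt, dam_gt)], "sire", "dam", CFG) == []


def test_low_quality_parent_excluded():
    s = trio_site(("A", "A"), ("G", "G"))
    s.site.calls["dam"] = SampleCall(("G", "G"), gq=19, dp=40)
    assert find_informative_snps([s], "sire", "dam", CFG) == []


def test_mendelian_violation_excluded_when_offspring_given():
    ok = trio_site(("A", "A"), ("G", "G"), off_gt=("A", "G"), pos=100)
    bad = trio_site(("A", "A"), ("G", "G"), off_gt=("A", "A"), pos=200)
    got = find_informative_snps([ok, bad], "sire", "dam", CFG, offspring="offspring")
    assert [s.site.pos for s in got] == [100]
    # without the offspring cross-check, both qualify
    got2 = find_informative_snps([ok, bad], "sire", "dam", CFG)
    assert len(got2) == 2


def test_absent_parents_named_failure():
    s = trio_site(("A", "A"), ("G", "G"))
    from triomae.trio import MissingParentError

    with pytest.raises(MissingParentError):
        find_informative_snps([s], "bull", "cow", CFG)


def _informative(maternal="G", paternal="A"):
    site = VariantSite(chrom="1", pos=100, ref="A", alt="G")
    return InformativeSNP(
        site=site, gene=GENE, maternal_allele=maternal, paternal_allele=paternal
    )


class TestClassifyExpressedAllele:
    def test_homozygous_maternal(self):
        snp = _informative()
        assert classify_expressed_allele(snp, SampleCall(("G", "G"), 60, 45), CFG) == MATERNAL

    def test_heterozygous_is_biallelic(self):
        snp = _informative()
        assert classify_expressed_allele(snp, SampleCall(("A", "G"), 60, 45), CFG) == BIALLELIC

    def test_low_depth_not_callable(self):
        snp = _informative()
        assert (
            classify_expressed_allele(snp, SampleCall(("G", "G"), 60, 5), CFG)
            == NOT_CALLABLE
        )

    def test_absent_call_not_callable(self):
        assert classify_expressed_allele(_informative(), None, CFG) == NOT_CALLABLE

    def test_allelic_fraction_mode(self):
        # maternal = alt (G); 49 of 50 reads support alt: fraction 0.98 >= 0.95
        snp = _informative()
        call = SampleCall(("A", "G"), 60, 50, ad=(1, 49))
        got = classify_expressed_allele(snp, call, CFG, mode="allelic_fraction")
        assert got == MATERNAL

    def test_allelic_fraction_balanced_is_biallelic(self):
        snp = _informative()
        call = SampleCall(("A", "G"), 60, 50, ad=(25, 25))
        got = classify_expressed_allele(snp, call, CFG, mode="allelic_fraction")
        assert got == BIALLELIC

    def test_allelic_fraction_requires_ad(self):
        snp = _informative()
        with pytest.raises(MissingAdError):
            classify_expressed_allele(
                snp, SampleCall(("G", "G"), 60, 45), CFG, mode="allelic_fraction"
            )


def _statuses(*vals, tissue="muscle"):
    return [
        SampleExpressionStatus(f"s{i}", tissue, v) for i, v in enumerate(vals)
    ]


@pytest.mark.parametrize(
    "vals,expect",
    [
        ((MATERNAL, MATERNAL), MATERNAL),
        ((MATERNAL, NOT_CALLABLE), MATERNAL),  # one callable sample suffices
        ((MATERNAL, BIALLELIC), CONFLICTING),
        ((MATERNAL, PATERNAL), CONFLICTING),
        ((BIALLELIC, BIALLELIC), BIALLELIC),
        ((NOT_CALLABLE, NOT_CALLABLE), NOT_CALLABLE),
    ],
)
def test_aggregate_tissue_rules(vals, expect):
    assert aggregate_tissue(_statuses(*vals)) == expect


def test_aggregate_tissue_rejects_mixed_tissues():
    statuses = _statuses(MATERNAL) + _statuses(MATERNAL, tissue="fat")
    with pytest.raises(MixedTissueError):
        aggregate_tissue(statuses)


def _call(status, tissue, snp=None):
    return MAECall(snp=snp or _informative(), tissue_type=tissue, status=status)


def test_aggregate_gene_all_tissue_maternal():
    calls = [_call(MATERNAL, t) for t in ("muscle", "fat", "brain")]
    prof = aggregate_gene(calls)
    assert prof.tissue_status == {t: MATERNAL for t in ("muscle", "fat", "brain")}
    assert prof.overall_origin == MATERNAL


def test_aggregate_gene_tissue_specific():
    calls = [
        _call(MATERNAL, "muscle"),
        _call(BIALLELIC, "fat"),
        _call(BIALLELIC, "brain"),
    ]
    prof = aggregate_gene(calls)
    assert prof.overall_origin == MATERNAL
    assert prof.mae_tissues == ["muscle"]


def test_aggregate_gene_contradictory_snps():
    calls = [_call(MATERNAL, "muscle"), _call(PATERNAL, "muscle")]
    prof = aggregate_gene(calls)
    assert prof.tissue_status["muscle"] == CONFLICTING
    # a conflicting tissue contributes no origin
    assert prof.overall_origin == "none"


def test_aggregate_gene_opposite_origins_in_different_tissues():
    calls = [_call(MATERNAL, "muscle"), _call(PATERNAL, "fat")]
    assert aggregate_gene(calls).overall_origin == "inconsistent"


def test_summarize_published_profiles():
    """The packaged 14-gene profile yields 14 MAE genes, 7 maternal, 7 paternal."""
    summary = summarize_mae(fixtures.mae_gene_profiles())
    assert summary.n_mae_genes == 14
    assert summary.n_maternal == 7
    assert summary.n_paternal == 7
    assert sorted(summary.tissue_specific["muscle"]) == ["DAPK2", "PDCL3"]
    assert sorted(summary.tissue_specific["fat"]) == ["ACKR3", "APLF", "N6AMT1"]
    assert sorted(summary.tissue_specific["brain"]) == ["OCIAD2", "PDIA4", "ZNF470"]


def test_summarize_empty():
    s = summarize_mae([])
    assert s.n_mae_genes == 0 and s.n_maternal == 0 and s.n_paternal == 0


def test_summarize_counts_planted_origins(bundle40, result40):
    """Noiseless-limit check: planted maternal/paternal gene counts recovered."""
    imp = bundle40.truth.imprinted_genes()
    summary = result40.summary
    assert summary["n_maternal"] == int((imp["origin"] == "maternal").sum())
    assert summary["n_paternal"] == int((imp["origin"] == "paternal").sum())


def test_label_symmetry_unit():
    """Swapping sire and dam flips maternal and paternal alleles."""
    sites = [trio_site(("A", "A"), ("G", "G"))]
    fwd = find_informative_snps(sites, "sire", "dam", CFG)
    rev = find_informative_snps(sites, "dam", "sire", CFG)
    assert fwd[0].maternal_allele == rev[0].paternal_allele
    assert fwd[0].paternal_allele == rev[0].maternal_allele
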