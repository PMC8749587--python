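"""Synthetic-data generator: determinism, Mendelian validity, planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomae import (
    FilterConfig,
    SimConfig,
    audit_bundle,
    find_informative_snps,
    read_annotation,
    read_vcf,
    run_pipeline,
    simulate_bundle,
    simulate_rna,
    simulate_trio,
)
from triomae.filters import exonic_filter, hard_filter
from triomae.io import SampleCall
from triomae.simulate import InfeasibleConfigError, SAMPLE_TISSUES, _call_from_reads
from .conftest import make_run_config


def test_same_seed_byte_identical(tmp_path):
    cfg = SimConfig(seed=123, n_genes=8)
    b1 = simulate_bundle(cfg, tmp_path / "a")
    b2 = simulate_bundle(SimConfig(seed=123, n_genes=8), tmp_path / "b")
    for p1, p2 in [
        (b1.sire_vcf, b2.sire_vcf),
        (b1.dam_vcf, b2.dam_vcf),
        (b1.offspring_vcf, b2.offspring_vcf),
        (b1.annotation, b2.annotation),
        (b1.genotypes_tsv, b2.genotypes_tsv),
        (b1.bvs_tsv, b2.bvs_tsv),
        *[(b1.rna_vcfs[s], b2.rna_vcfs[s]) for s in SAMPLE_TISSUES],
    ]:
        assert p1.read_bytes() == p2.read_bytes(), p1.name


def test_different_seed_differs(tmp_path):
    b1 = simulate_trio(SimConfig(seed=1, n_genes=8), tmp_path / "a")
    b2 = simulate_trio(SimConfig(seed=2, n_genes=8), tmp_path / "b")
    assert b1.sire_vcf.read_bytes() != b2.sire_vcf.read_bytes()


def test_bundle_self_consistency_audit(bundle40):
    report = audit_bundle(bundle40)
    assert report["n_snps_checked"] == len(bundle40.truth.snps)


def test_mendelian_validity_of_planted_genotypes(bundle40):
    snps = bundle40.truth.snps
    for row in snps.itertuples():
        assert row.off_paternal in row.sire_gt.split("/")
        assert row.off_maternal in row.dam_gt.split("/")


def test_infeasible_configs_rejected():
    with pytest.raises(InfeasibleConfigError):
        SimConfig(n_genes=0)
    with pytest.raises(InfeasibleConfigError):
        SimConfig(frac_informative=1.5)
    with pytest.raises(InfeasibleConfigError):
        SimConfig(tissue_pattern_probs={"all_tissues": 0.5})


def test_all_informative_config_recovered_exactly(tmp_path):
    """frac_informative=1, no errors, no filter failures: find_informative_snps
    returns exactly the planted informative set."""
    cfg = SimConfig(
        seed=7, n_genes=20, frac_informative=1.0, frac_imprinted_genes=0.0,
        base_error_rate=0.0, frac_fail_hard_filter=0.0, frac_non_exonic=0.0,
        depth_mean_dna=40.0,
    )
    bundle = simulate_trio(cfg, tmp_path)
    assert bundle.truth.snps["informative"].all()
    ann = read_annotation(bundle.annotation)
    sites = {}
    for path in (bundle.sire_vcf, bundle.dam_vcf, bundle.offspring_vcf):
        for s in read_vcf(path).sites:
            key = (s.chrom, s.pos)
            if key in sites:
                calls = dict(sites[key].calls)
                calls.update(s.calls)
                sites[key] = type(s)(chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                                     snp_id=s.snp_id, metrics=s.metrics, calls=calls)
            else:
                sites[key] = s
    fcfg = FilterConfig()
    annotated = exonic_filter(
        [s for s in sites.values() if hard_filter(s, fcfg)[0]], ann, fcfg
    )
    informative = find_informative_snps(annotated, "sire", "dam", fcfg, offspring="offspring")
    got = {(i.site.chrom, i.site.pos): (i.maternal_allele, i.paternal_allele)
           for i in informative}
    want = {
        (str(r.chrom), int(r.pos)): (r.maternal_allele, r.paternal_allele)
        for r in bundle.truth.snps.itertuples()
    }
    assert got == want


def test_hard_filter_failure_fraction(tmp_path):
    """~20% of sites get exactly one violated metric (binomial tolerance)."""
    cfg = SimConfig(
        seed=13, n_genes=60, snps_per_gene_mean=5.0, frac_imprinted_genes=0.0,
        frac_fail_hard_filter=0.2,
    )
    bundle = simulate_trio(cfg, tmp_path)
    snps = bundle.truth.snps
    n = len(snps)
    frac = snps["fails_hard_filter"].mean()
    se = np.sqrt(0.2 * 0.8 / n)
    assert abs(frac - 0.2) < 4 * se
    # flags agree with the hard filter applied to the emitted metrics
    failing = snps[snps["fails_hard_filter"]]
    sites = {(s.chrom, s.pos): s for s in read_vcf(bundle.sire_vcf).sites}
    for row in failing.itertuples():
        passed, failed = hard_filter(sites[(str(row.chrom), int(row.pos))])
        assert not passed and failed == [row.failed_metric]


def test_noiseless_imprinted_gene_rna_calls(tmp_path):
    """Error 0, depth 50: covered tissues call homozygous for the expressed
    allele in both samples; biallelic sites give balanced AD and het calls."""
    cfg = SimConfig(
        seed=3, n_genes=10, frac_imprinted_genes=1.0, frac_informative=1.0,
        base_error_rate=0.0, depth_mean_rna=50.0, frac_fail_hard_filter=0.0,
        tissue_pattern_probs={"all_tissues": 1.0, "muscle_only": 0.0,
                              "fat_only": 0.0, "brain_only": 0.0, "two_tissues": 0.0},
    )
    bundle = simulate_trio(cfg, tmp_path)
    simulate_rna(cfg, bundle)
    truth = bundle.truth
    origin_of = truth.genes.set_index("gene_id")["origin"]
    snp_info = truth.snps.set_index(["chrom", "pos"])
    for sample in SAMPLE_TISSUES:
        for site in read_vcf(bundle.rna_vcfs[sample]).sites:
            row = snp_info.loc[(site.chrom, site.pos)]
            expressed = (
                row["maternal_allele"]
                if origin_of[row["gene_id"]] == "maternal"
                else row["paternal_allele"]
            )
            call = site.call(sample)
            if call.dp == 0:
                continue
            assert call.is_hom and call.hom_allele == expressed


def test_noiseless_biallelic_ad_near_half(tmp_path):
    cfg = SimConfig(
        seed=9, n_genes=30, frac_imprinted_genes=0.0, frac_informative=1.0,
        base_error_rate=0.0, depth_mean_rna=50.0,
    )
    bundle = simulate_trio(cfg, tmp_path)
    simulate_rna(cfg, bundle)
    fracs = []
    for site in read_vcf(bundle.rna_vcfs["fat_back"]).sites:
        call = site.call("fat_back")
        if call.dp >= 20:
            assert call.is_het
            fracs.append(call.ad[1] / call.dp)
    assert abs(np.mean(fracs) - 0.5) < 0.05


def test_population_hwe_sanity(tmp_path):
    from triomae.io import read_population
    from triomae.simulate import simulate_population

    cfg = SimConfig(seed=21, pop_n=203, pop_maf=0.2)
    gp, bp, _ = simulate_population(cfg, [f"s{i}" for i in range(50)], tmp_path)
    pop = read_population(gp, bp)
    p = cfg.pop_maf
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) * cfg.pop_n
    pvals = []
    for snp in pop.snp_ids:
        obs = pop.genotypes[snp].value_counts().reindex(["AA", "AB", "BB"]).fillna(0)
        chi2 = ((obs.to_numpy() - expected) ** 2 / expected).sum()
        pvals.append(stats.chi2.sf(chi2, df=2))
    # distributional sanity, not a hard per-SNP gate
    assert np.mean(np.array(pvals) < 0.01) < 0.2


def test_caller_emulation_basics():
    call = _call_from_reads(40, 0, "A", "G", 0.001, 0.1)
    assert call.genotype == ("A", "A") and call.gq >= 20
    call = _call_from_reads(20, 20, "A", "G", 0.001, 0.1)
    assert call.genotype == ("A", "G")
    assert _call_from_reads(0, 0, "A", "G", 0.001, 0.1).genotype is None
    # threshold behaviour: 3 minor reads in 40 is below 0.1 -> homozygous
    assert _call_from_reads(37, 3, "A", "G", 0.001, 0.1).genotype == ("A", "A")


def _recovery_counts(tmp_path, error_rates):
    counts = []
    for i, e in enumerate(error_rates):
        cfg = SimConfig(
            seed=97, n_genes=24, frac_imprinted_genes=0.5, base_error_rate=e,
            depth_mean_rna=60.0,
        )
        bundle = simulate_bundle(cfg, tmp_path / f"err{i}")
        res = run_pipeline(
            make_run_config(bundle, tmp_path / f"run{i}")
        )
        planted = {
            r.gene_id: (r.origin, sorted(str(r.pattern).split(";")))
            for r in bundle.truth.imprinted_genes().itertuples()
        }
        recovered = {
            p.gene_id: (p.overall_origin, sorted(p.mae_tissues))
            for p in res.profiles
            if p.is_mae
        }
        counts.append(sum(1 for g, v in planted.items() if recovered.get(g) == v))
    return counts


def test_recovery_degrades_with_base_error(tmp_path):
    """Recovered planted-gene count is non-increasing in the base-error rate."""
    counts = _recovery_counts(tmp_path, [0.0, 0.02, 0.06, 0.12, 0.3])
    assert counts[0] == 12  # all planted genes at zero error
    for a, b in zip(counts, counts[1:]):
        assert b <= a
    assert counts[-1] < counts[0]
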