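import pytest

from triomae import RunConfig, SimConfig, run_pipeline, simulate_bundle
from triomae.simulate import SAMPLE_TISSUES


def make_run_config(bundle, outdir, swap_parents=False, **kwargs):
    """Build a RunConfig pointing at a simulated bundle's files."""
    dna = {
        "sire": str(bundle.sire_vcf),
        "dam": str(bundle.dam_vcf),
        "offspring": str(bundle.offspring_vcf),
    }
    if swap_parents:
        dna["sire"], dna["dam"] = dna["dam"], dna["sire"]
    cfg = RunConfig(
        dna_vcfs=dna,
        rna_vcfs={s: str(p) for s, p in bundle.rna_vcfs.items()},
        sample_tissues=dict(SAMPLE_TISSUES),
        annotation=str(bundle.annotation),
        outdir=str(outdir),
        genotypes=str(bundle.genotypes_tsv) if bundle.genotypes_tsv else None,
        bvs=str(bundle.bvs_tsv) if bundle.bvs_tsv else None,
        **kwargs,
    )
    return cfg


@pytest.fixture(scope="session")
def bundle40(tmp_path_factory):
    """The standard synthetic study: 40 genes, 8 imprinted, 60x RNA, 0.1% error."""
    cfg = SimConfig(seed=11, n_genes=40)
    return simulate_bundle(cfg, tmp_path_factory.mktemp("bundle40"))


@pytest.fixture(scope="session")
def result40(bundle40, tmp_path_factory):
    cfg = make_run_config(bundle40, tmp_path_factory.mktemp("run40"))
    return run_pipeline(cfg)
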