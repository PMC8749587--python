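"""End-to-end orchestration: filter → informative SNPs → MAE calls →
gene profiles → (optional) breeding-value association, with a manifest
recording every stage's input/output counts.

The run starts from called VCFs; read alignment and variant calling are
upstream of this package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .association import associate_all, lsmeans_to_frame, results_to_frame
from .filters import FilterConfig, exonic_filter, hard_filter
from .io import read_annotation, read_population, read_vcf
from .trio import (
    GeneMAEProfile,
    MAECall,
    ORIGINS,
    call_mae,
    find_informative_snps,
    summarize_mae,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid before any compute starts."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All inputs and settings of one pipeline run."""

    dna_vcfs: dict  # role -> path; roles: sire, dam, offspring (offspring optional)
    rna_vcfs: dict  # sample name -> path
    sample_tissues: dict  # sample name -> tissue type
    annotation: str
    outdir: str
    genotypes: Optional[str] = None
    bvs: Optional[str] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    expression_mode: str = "genotype"  # or "allelic_fraction"
    af_threshold: float = 0.95
    alpha: float = 0.05
    freq_threshold: float = 0.10
    mendelian_check: bool = True

    def validate(self) -> None:
        for role in ("sire", "dam"):
            if role not in self.dna_vcfs:
                raise ConfigError(f"DNA VCF role {role!r} missing")
        unmapped = set(self.rna_vcfs) - set(self.sample_tissues)
        if unmapped:
            raise ConfigError(f"RNA sample(s) without tissue mapping: {sorted(unmapped)}")
        if self.expression_mode not in ("genotype", "allelic_fraction"):
            raise ConfigError(f"unknown expression_mode {self.expression_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filters = FilterConfig.from_dict(raw.pop("filters", {}) or {})
        return cls(filters=filters, **raw)


@dataclass
class PipelineResult:
    """Everything one run produced, in memory plus on disk under ``outdir``."""

    counts: dict
    mae_calls: list
    profiles: list
    summary: dict
    association: Optional[pd.DataFrame]
    outdir: Path


def _profiles_frame(profiles: list[GeneMAEProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "gene_id": p.gene_id,
                "gene_symbol": p.gene_symbol,
                "chrom": p.chrom,
                "muscle": p.tissue_status.get("muscle", "not_callable"),
                "fat": p.tissue_status.get("fat", "not_callable"),
                "brain": p.tissue_status.get("brain", "not_callable"),
                "overall_origin": p.overall_origin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_symbol", "chrom", "muscle", "fat", "brain", "overall_origin"],
    )


def _calls_frame(calls: list[MAECall]) -> pd.DataFrame:
    rows = []
    keys = {}
    for c in calls:
        key = (c.snp.site.chrom, c.snp.site.pos)
        keys.setdefault(key, {"snp": c.snp})
        keys[key][c.tissue_type] = c.status
    for (chrom, pos), d in sorted(keys.items(), key=lambda kv: (int(kv[0][0]) if str(kv[0][0]).isdigit() else 0, kv[0][0], kv[0][1])):
        snp = d["snp"]
        rows.append(
            {
                "snp_id": snp.site.snp_id or f"{chrom}:{pos}",
                "chrom": chrom,
                "pos": pos,
                "gene_id": snp.gene.gene_id,
                "gene_symbol": snp.gene.gene_symbol,
                "consequence": snp.gene.consequence,
                "maternal_allele": snp.maternal_allele,
                "paternal_allele": snp.paternal_allele,
                "muscle": d.get("muscle", "not_callable"),
                "fat": d.get("fat", "not_callable"),
                "brain": d.get("brain", "not_callable"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "gene_id", "gene_symbol", "consequence",
                 "maternal_allele", "paternal_allele", "muscle", "fat", "brain"],
    )


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full pipeline and write the report bundle.

    Outputs under ``cfg.outdir``: informative_snps.tsv, mae_snps.tsv (one row
    per informative SNP with per-tissue status), mae_genes.tsv (the gene ×
    tissue matrix), summary.json, association.tsv + lsmeans.tsv when a
    population is supplied, and manifest.json with the stage-count funnel.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    try:
        annotation = read_annotation(cfg.annotation)
        dna = {}
        for role, path in cfg.dna_vcfs.items():
            dna[role] = read_vcf(path, required_samples=None)
        counts["dna_records_dropped"] = {
            role: {"multiallelic": r.n_multiallelic, "indel": r.n_indel}
            for role, r in dna.items()
        }
    except Exception as exc:
        raise StageError(f"stage=read_inputs: {exc}") from exc

    # merge the per-role DNA VCFs on site keys; each contributes its sample call
    try:
        merged: dict = {}
        role_sample = {}
        for role, res in dna.items():
            for site in res.sites:
                key = (site.chrom, site.pos, site.ref, site.alt)
                if key not in merged:
                    merged[key] = site
                else:
                    calls = dict(merged[key].calls)
                    calls.update(site.calls)
                    merged[key] = type(site)(
                        chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
                        snp_id=site.snp_id, metrics=site.metrics, calls=calls,
                    )
            samples = {name for s in res.sites for name in s.calls}
            if len(samples) == 1:
                role_sample[role] = samples.pop()
            else:
                role_sample[role] = role
        sites = list(merged.values())
        counts["total_sites"] = len(sites)
    except Exception as exc:
        raise StageError(f"stage=merge_trio: {exc}") from exc

    try:
        hard_pass = [s for s in sites if hard_filter(s, cfg.filters)[0]]
        counts["hard_filter_pass"] = len(hard_pass)
        exonic = exonic_filter(hard_pass, annotation, cfg.filters)
        counts["exonic"] = len(exonic)
    except Exception as exc:
        raise StageError(f"stage=filter: {exc}") from exc

    try:
        offspring = role_sample.get("offspring") if cfg.mendelian_check else None
        informative = find_informative_snps(
            exonic, sire=role_sample["sire"], dam=role_sample["dam"],
            cfg=cfg.filters, offspring=offspring,
        )
        counts["informative"] = len(informative)
    except Exception as exc:
        raise StageError(f"stage=informative: {exc}") from exc

    try:
        rna_sites = {}
        for sample, path in cfg.rna_vcfs.items():
            res = read_vcf(path, required_samples=[sample])
            rna_sites[sample] = {
                (s.chrom, s.pos, s.ref, s.alt): s for s in res.sites
            }
        calls, profiles = call_mae(
            informative, rna_sites, cfg.sample_tissues, cfg.filters,
            mode=cfg.expression_mode, af_threshold=cfg.af_threshold,
        )
        mae_snp_keys = {
            (c.snp.site.chrom, c.snp.site.pos) for c in calls if c.status in ORIGINS
        }
        counts["mae_snps"] = len(mae_snp_keys)
        summary = summarize_mae(profiles, snp_calls=calls)
        counts["mae_genes"] = summary.n_mae_genes
    except Exception as exc:
        raise StageError(f"stage=call_mae: {exc}") from exc

    association_df = None
    if cfg.genotypes and cfg.bvs:
        try:
            pop = read_population(cfg.genotypes, cfg.bvs)
            results = associate_all(
                pop, alpha=cfg.alpha, freq_threshold=cfg.freq_threshold
            )
            association_df = results_to_frame(results)
            association_df.to_csv(outdir / "association.tsv", sep="\t", index=False)
            lsmeans_to_frame(results).to_csv(outdir / "lsmeans.tsv", sep="\t", index=False)
            counts["association_fits"] = int((association_df["status"] == "ok").sum())
            counts["association_significant"] = int(
                association_df["significant"].fillna(False).sum()
            )
        except Exception as exc:
            raise StageError(f"stage=associate: {exc}") from exc

    snp_table = _calls_frame(calls)
    gene_table = _profiles_frame(profiles)
    inf_rows = pd.DataFrame(
        [
            {
                "snp_id": i.site.snp_id or f"{i.site.chrom}:{i.site.pos}",
                "chrom": i.site.chrom,
                "pos": i.site.pos,
                "gene_id": i.gene.gene_id,
                "maternal_allele": i.maternal_allele,
                "paternal_allele": i.paternal_allele,
            }
            for i in informative
        ],
        columns=["snp_id", "chrom", "pos", "gene_id", "maternal_allele", "paternal_allele"],
    )
    inf_rows.to_csv(outdir / "informative_snps.tsv", sep="\t", index=False)
    snp_table.to_csv(outdir / "mae_snps.tsv", sep="\t", index=False)
    gene_table.to_csv(outdir / "mae_genes.tsv", sep="\t", index=False)
    summary_dict = summary.as_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_dict, fh, indent=2, sort_keys=True)
    manifest = {
        "tool": "triomae",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline funnel: %s", counts)
    return PipelineResult(
        counts=counts,
        mae_calls=calls,
        profiles=profiles,
        summary=summary_dict,
        association=association_df,
        outdir=outdir,
    )
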