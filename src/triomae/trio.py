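"""Parent-of-origin monoallelic-expression inference from a trio.

At a site where sire and dam are homozygous for opposite alleles, the
offspring is an obligate heterozygote and the parental origin of each of its
alleles is known without phasing. The RNA call at such an *informative SNP*
then tells which parental allele a tissue expresses: a homozygous RNA
genotype means monoallelic expression of that allele (maternal or paternal),
a heterozygous one means biallelic expression. Per-tissue and per-gene
profiles aggregate these calls, requiring unanimity among callable samples
before declaring MAE.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .filters import AnnotatedSite, FilterConfig, call_quality_ok
from .io import GeneAnnotation, SampleCall, VariantSite

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"
BIALLELIC = "biallelic"
CONFLICTING = "conflicting"
NOT_CALLABLE = "not_callable"

ORIGINS = (MATERNAL, PATERNAL)

#: Gene-level overall origin labels.
INCONSISTENT = "inconsistent"
NONE = "none"

TISSUE_TYPES = ("muscle", "fat", "brain")


class MissingParentError(KeyError):
    """Sire or dam has no call at any candidate site."""


class MissingAdError(ValueError):
    """Allelic-fraction classification requested but the call carries no AD."""


class MixedTissueError(ValueError):
    """Statuses from different tissue types handed to a per-tissue aggregation."""


@dataclass(frozen=True)
class InformativeSNP:
    """A SNP with opposite-homozygote parents: offspring alleles have known origin."""

    site: VariantSite
    gene: GeneAnnotation
    maternal_allele: str
    paternal_allele: str

    def __post_init__(self):
        if self.maternal_allele == self.paternal_allele:
            raise ValueError("parental alleles must differ")
        if set((self.maternal_allele, self.paternal_allele)) != set(self.site.alleles):
            raise ValueError("parental alleles must be exactly {ref, alt}")


@dataclass(frozen=True)
class SampleExpressionStatus:
    """Expressed-allele status of one RNA sample at one informative SNP."""

    sample_name: str
    tissue_type: str
    status: str


@dataclass(frozen=True)
class MAECall:
    """Tissue-level expressed-allele status at one informative SNP."""

    snp: InformativeSNP
    tissue_type: str
    status: str


@dataclass
class GeneMAEProfile:
    """Per-tissue MAE status of one gene and its overall parental origin."""

    gene_id: str
    gene_symbol: str
    tissue_status: dict = field(default_factory=dict)
    overall_origin: str = NONE
    chrom: Optional[str] = None

    @staticmethod
    def resolve_origin(tissue_status: Mapping[str, str]) -> str:
        has_m = MATERNAL in tissue_status.values()
        has_p = PATERNAL in tissue_status.values()
        if has_m and has_p:
            return INCONSISTENT
        if has_m:
            return MATERNAL
        if has_p:
            return PATERNAL
        return NONE

    @property
    def is_mae(self) -> bool:
        return self.overall_origin in ORIGINS

    @property
    def mae_tissues(self) -> list[str]:
        return [t for t, s in self.tissue_status.items() if s in ORIGINS]


def find_informative_snps(
    sites: Sequence[AnnotatedSite],
    sire: str,
    dam: str,
    cfg: FilterConfig = FilterConfig(),
    offspring: Optional[str] = None,
) -> list[InformativeSNP]:
    """Select sites where sire and dam are opposite homozygotes.

    Both parental DNA calls must pass the GQ/DP gate, be homozygous, and
    carry different alleles. The dam's allele becomes the maternal allele and
    the sire's the paternal one. When *offspring* is given and its DNA call
    passes quality, a non-heterozygous offspring call is a Mendelian
    violation: the site is excluded and counted in the log.
    """
    if sites and not any(s.site.call(sire) or s.site.call(dam) for s in sites):
        raise MissingParentError(f"neither {sire!r} nor {dam!r} has any call")
    out = []
    n_mendel = 0
    for asite in sites:
        site = asite.site
        sire_call = site.call(sire)
        dam_call = site.call(dam)
        if not (call_quality_ok(sire_call, cfg) and call_quality_ok(dam_call, cfg)):
            continue
        if not (sire_call.is_hom and dam_call.is_hom):
            continue
        if sire_call.hom_allele == dam_call.hom_allele:
            continue
        if offspring is not None:
            off_call = site.call(offspring)
            if call_quality_ok(off_call, cfg) and not off_call.is_het:
                n_mendel += 1
                logger.warning(
                    "Mendelian violation at %s:%d — opposite-homozygote parents "
                    "but offspring %s; site excluded",
                    site.chrom, site.pos, off_call.genotype,
                )
                continue
        out.append(
            InformativeSNP(
                site=site,
                gene=asite.gene,
                maternal_allele=dam_call.hom_allele,
                paternal_allele=sire_call.hom_allele,
            )
        )
    if n_mendel:
        logger.info("excluded %d site(s) with Mendelian violations", n_mendel)
    return out


def classify_expressed_allele(
    snp: InformativeSNP,
    rna_call: Optional[SampleCall],
    cfg: FilterConfig = FilterConfig(),
    mode: str = "genotype",
    af_threshold: float = 0.95,
) -> str:
    """Classify which parental allele an RNA sample expresses at one SNP.

    In ``genotype`` mode (default) the RNA genotype call decides: homozygous
    for the maternal (paternal) allele means maternal (paternal) expression,
    heterozygous means biallelic. In ``allelic_fraction`` mode the AD read
    counts decide: a parental allele supported by at least *af_threshold* of
    the reads is called as the expressed allele, anything else is biallelic.
    Calls failing the GQ/DP gate (or absent) are ``not_callable``.
    """
    if not call_quality_ok(rna_call, cfg):
        return NOT_CALLABLE
    if mode == "genotype":
        if rna_call.is_hom:
            if rna_call.hom_allele == snp.maternal_allele:
                return MATERNAL
            return PATERNAL
        return BIALLELIC
    if mode == "allelic_fraction":
        if rna_call.ad is None:
            raise MissingAdError("allelic_fraction mode requires AD counts")
        total = sum(rna_call.ad)
        if total == 0:
            return NOT_CALLABLE
        ref_frac = rna_call.ad[0] / total
        frac = {snp.site.ref: ref_frac, snp.site.alt: 1.0 - ref_frac}
        if frac[snp.maternal_allele] >= af_threshold:
            return MATERNAL
        if frac[snp.paternal_allele] >= af_threshold:
            return PATERNAL
        return BIALLELIC
    raise ValueError(f"unknown mode {mode!r}")


def _aggregate_statuses(statuses: Iterable[str]) -> str:
    """Unanimity-over-callable rule shared by tissue- and gene-level rollups."""
    callable_ = [s for s in statuses if s != NOT_CALLABLE]
    if not callable_:
        return NOT_CALLABLE
    if any(s in ORIGINS for s in callable_):
        uniq = set(callable_)
        if len(uniq) == 1:
            return callable_[0]
        return CONFLICTING
    if any(s == CONFLICTING for s in callable_):
        return CONFLICTING
    return BIALLELIC


def aggregate_tissue(statuses: Sequence[SampleExpressionStatus]) -> str:
    """Combine the samples of one tissue type into one SNP-level status.

    Not-callable samples are dropped; one callable sample suffices. Unanimity
    among the callable samples yields that status; an origin call plus any
    disagreeing callable sample yields ``conflicting`` — never MAE.
    """
    tissues = {s.tissue_type for s in statuses}
    if len(tissues) > 1:
        raise MixedTissueError(f"mixed tissue types: {sorted(tissues)}")
    return _aggregate_statuses(s.status for s in statuses)


def aggregate_gene(calls: Sequence[MAECall]) -> GeneMAEProfile:
    """Roll SNP × tissue calls for one gene up to a gene × tissue profile."""
    genes = {c.snp.gene.gene_id for c in calls}
    if len(genes) != 1:
        raise ValueError(f"calls must share one gene_id, got {sorted(genes)}")
    first = calls[0].snp.gene
    per_tissue: dict[str, list[str]] = defaultdict(list)
    for c in calls:
        per_tissue[c.tissue_type].append(c.status)
    tissue_status = {t: _aggregate_statuses(v) for t, v in per_tissue.items()}
    return GeneMAEProfile(
        gene_id=first.gene_id,
        gene_symbol=first.gene_symbol,
        tissue_status=tissue_status,
        overall_origin=GeneMAEProfile.resolve_origin(tissue_status),
        chrom=calls[0].snp.site.chrom,
    )


@dataclass
class MAESummary:
    """Headline counts over a set of gene profiles."""

    n_genes_evaluated: int
    n_mae_genes: int
    n_maternal: int
    n_paternal: int
    n_inconsistent: int
    n_chromosomes: int
    tissue_specific: dict
    consequence_counts: dict

    def as_dict(self) -> dict:
        return {
            "n_genes_evaluated": self.n_genes_evaluated,
            "n_mae_genes": self.n_mae_genes,
            "n_maternal": self.n_maternal,
            "n_paternal": self.n_paternal,
            "n_inconsistent": self.n_inconsistent,
            "n_chromosomes": self.n_chromosomes,
            "tissue_specific": self.tissue_specific,
            "consequence_counts": self.consequence_counts,
        }


def summarize_mae(
    profiles: Sequence[GeneMAEProfile],
    snp_calls: Optional[Sequence[MAECall]] = None,
) -> MAESummary:
    """Count MAE genes by origin, chromosome span, tissue specificity.

    When SNP-level calls are supplied, SNPs showing MAE in at least one
    tissue are additionally tallied by molecular consequence.
    """
    mae = [p for p in profiles if p.is_mae]
    tissue_specific = {t: [] for t in TISSUE_TYPES}
    for p in mae:
        ts = p.mae_tissues
        if len(ts) == 1 and ts[0] in tissue_specific:
            tissue_specific[ts[0]].append(p.gene_symbol or p.gene_id)
    chroms = {p.chrom for p in mae if p.chrom is not None}
    consequence_counts: dict[str, int] = {}
    if snp_calls is not None:
        mae_snp_keys = {}
        for c in snp_calls:
            if c.status in ORIGINS:
                key = (c.snp.site.chrom, c.snp.site.pos)
                mae_snp_keys[key] = c.snp.gene.consequence
        for cons in mae_snp_keys.values():
            consequence_counts[cons] = consequence_counts.get(cons, 0) + 1
    return MAESummary(
        n_genes_evaluated=len(profiles),
        n_mae_genes=len(mae),
        n_maternal=sum(p.overall_origin == MATERNAL for p in mae),
        n_paternal=sum(p.overall_origin == PATERNAL for p in mae),
        n_inconsistent=sum(p.overall_origin == INCONSISTENT for p in profiles),
        n_chromosomes=len(chroms),
        tissue_specific=tissue_specific,
        consequence_counts=consequence_counts,
    )


def call_mae(
    informative: Sequence[InformativeSNP],
    rna_sites: Mapping[str, Mapping[tuple, VariantSite]],
    sample_tissues: Mapping[str, str],
    cfg: FilterConfig = FilterConfig(),
    mode: str = "genotype",
    af_threshold: float = 0.95,
) -> tuple[list[MAECall], list[GeneMAEProfile]]:
    """Run classification and both aggregation levels over all samples.

    *rna_sites* maps sample name → {(chrom, pos, ref, alt) → VariantSite}
    from that sample's RNA VCF (sites absent from a sample's VCF are
    not_callable for it).
    """
    calls: list[MAECall] = []
    by_gene: dict[str, list[MAECall]] = defaultdict(list)
    tissues_of = defaultdict(list)
    for sample, tissue in sample_tissues.items():
        tissues_of[tissue].append(sample)
    for snp in informative:
        key = (snp.site.chrom, snp.site.pos, snp.site.ref, snp.site.alt)
        for tissue, samples in tissues_of.items():
            statuses = []
            for sample in samples:
                site = rna_sites.get(sample, {}).get(key)
                rna_call = site.call(sample) if site is not None else None
                status = classify_expressed_allele(
                    snp, rna_call, cfg, mode=mode, af_threshold=af_threshold
                )
                statuses.append(SampleExpressionStatus(sample, tissue, status))
            call = MAECall(snp=snp, tissue_type=tissue, status=aggregate_tissue(statuses))
            calls.append(call)
            by_gene[snp.gene.gene_id].append(call)
    profiles = [aggregate_gene(v) for v in by_gene.values()]
    profiles.sort(key=lambda p: p.gene_id)
    return calls, profiles
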