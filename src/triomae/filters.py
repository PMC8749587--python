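"""Site-level hard filters, exonic screening, and per-call quality gates.

The hard filter reproduces the standard GATK hard-filtering recipe for SNPs:
a site is removed when QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < -12.5 or
ReadPosRankSum < -8.0. All five comparisons are strict, so a value exactly at
its threshold passes. Rank-sum metrics are legitimately absent at sites
without heterozygous calls, and an absent metric never fails the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional

from .io import CONSEQUENCES, GeneAnnotation, SampleCall, VariantSite

EXONIC_CLASSES = frozenset({"missense", "synonymous", "utr3", "utr5", "other_exonic"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for site and call filtering.

    Attributes
    ----------
    qd_min, fs_max, mq_min, mqranksum_min, readposranksum_min:
        Hard-filter thresholds on the site INFO metrics (strict comparisons;
        a site fails on QD < qd_min, FS > fs_max, MQ < mq_min,
        MQRankSum < mqranksum_min, ReadPosRankSum < readposranksum_min).
    gq_min, dp_min:
        Per-sample genotype-quality and depth gates, inclusive (GQ >= 20,
        DP >= 10 by default), applied to parental DNA calls when selecting
        informative SNPs and to each RNA call when classifying expression.
    exonic_classes:
        Consequence labels counted as exonic.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    gq_min: int = 20
    dp_min: int = 10
    exonic_classes: frozenset = field(default_factory=lambda: EXONIC_CLASSES)

    def __post_init__(self):
        object.__setattr__(self, "exonic_classes", frozenset(self.exonic_classes))
        if "non_exonic" in self.exonic_classes:
            raise ValueError("exonic_classes cannot contain 'non_exonic'")
        unknown = self.exonic_classes - set(CONSEQUENCES)
        if unknown:
            raise ValueError(f"unknown consequence label(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown filter key(s): {sorted(unknown)}")
        return cls(**d)


def hard_filter(site: VariantSite, cfg: FilterConfig = FilterConfig()) -> tuple[bool, list[str]]:
    """Evaluate the five-metric hard filter on one site.

    Returns ``(passed, failed_metrics)``. Only metrics present on the site
    are tested; an absent metric cannot fail.
    """
    m = site.metrics
    failed = []
    if "QD" in m and m["QD"] < cfg.qd_min:
        failed.append("QD")
    if "FS" in m and m["FS"] > cfg.fs_max:
        failed.append("FS")
    if "MQ" in m and m["MQ"] < cfg.mq_min:
        failed.append("MQ")
    if "MQRankSum" in m and m["MQRankSum"] < cfg.mqranksum_min:
        failed.append("MQRankSum")
    if "ReadPosRankSum" in m and m["ReadPosRankSum"] < cfg.readposranksum_min:
        failed.append("ReadPosRankSum")
    return (not failed, failed)


@dataclass(frozen=True)
class AnnotatedSite:
    """A site that survived exonic screening, tagged with its gene."""

    site: VariantSite
    gene: GeneAnnotation


def annotate_site(site: VariantSite, annotation: Mapping) -> GeneAnnotation:
    """Look a site up in the annotation map; unannotated sites are non-exonic."""
    key = (site.chrom, site.pos, site.ref, site.alt)
    ga = annotation.get(key)
    if ga is None:
        return GeneAnnotation(gene_id="", gene_symbol="", consequence="non_exonic")
    return ga


def exonic_filter(
    sites: Iterable[VariantSite],
    annotation: Mapping,
    cfg: FilterConfig = FilterConfig(),
) -> list[AnnotatedSite]:
    """Keep sites whose consequence is exonic, tagging each with its gene."""
    out = []
    for site in sites:
        ga = annotate_site(site, annotation)
        if ga.consequence in cfg.exonic_classes:
            out.append(AnnotatedSite(site=site, gene=ga))
    return out


def call_quality_ok(call: Optional[SampleCall], cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff the call has a genotype and passes GQ >= gq_min, DP >= dp_min."""
    return (
        call is not None
        and not call.is_missing
        and call.gq >= cfg.gq_min
        and call.dp >= cfg.dp_min
    )
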