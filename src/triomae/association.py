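"""Association of SNP genotypes with estimated breeding values.

The model is the one-way fixed-effect general linear model
``y_ij = mu + G_i + e_ij`` — breeding value as the response, genotype class
as the single fixed factor, no covariates. With one factor, the overall
genotype F test is the ordinary one-way ANOVA F, and the least-square mean
of each genotype class is its raw class mean with standard error
sqrt(MS_within / n_class). Genotype classes rarer than the frequency
threshold (strictly below 10% by default) are excluded from the fit at that
locus, and no multiple-testing correction is applied to the reported
p-values (a Bonferroni column is emitted for information only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GENOTYPE_CODES, TRAITS, PopulationData

logger = logging.getLogger(__name__)


class AllMissingError(ValueError):
    """Every animal is missing a genotype at the requested SNP."""


class DegenerateFitError(ValueError):
    """The model cannot be fit (too few classes or animals)."""


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Genotype counts and frequencies at one SNP.

    Frequencies are exact (count / non-missing total); ``display`` rounds to
    the 2 decimals used in reports. ``relabelled`` flags loci where the B
    allele in the input was in fact the major allele, in which case AA and BB
    are swapped so that B is always the minor allele.
    """

    snp_id: str
    counts: dict
    n: int
    relabelled: bool = False

    @property
    def freqs(self) -> dict:
        return {g: c / self.n for g, c in self.counts.items()}

    def display(self) -> dict:
        return {g: round(f, 2) for g, f in self.freqs.items()}


def genotype_frequencies(pop: PopulationData, snp_id: str) -> GenotypeFrequencies:
    """Count AA/AB/BB at one SNP, relabelling so B is the minor allele."""
    col = pop.genotypes[snp_id].dropna()
    n = len(col)
    if n == 0:
        raise AllMissingError(f"all genotypes missing at {snp_id}")
    counts = {g: int((col == g).sum()) for g in GENOTYPE_CODES}
    b_alleles = counts["AB"] + 2 * counts["BB"]
    relabelled = b_alleles > n  # freq(B) > 0.5
    if relabelled:
        counts["AA"], counts["BB"] = counts["BB"], counts["AA"]
        logger.warning("B was the major allele at %s; AA/BB relabelled", snp_id)
    return GenotypeFrequencies(snp_id=snp_id, counts=counts, n=n, relabelled=relabelled)


def exclude_rare_genotypes(
    freqs: GenotypeFrequencies, threshold: float = 0.10
) -> tuple[list[str], list[str]]:
    """Split genotype classes into (retained, excluded) by frequency.

    A class is excluded iff its frequency is strictly below *threshold*;
    a class at exactly the threshold is retained.
    """
    retained, excluded = [], []
    for g in GENOTYPE_CODES:
        (excluded if freqs.freqs[g] < threshold else retained).append(g)
    return retained, excluded


@dataclass
class GlmFit:
    """Core numbers of one one-way fixed-effect fit."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    n_used: int
    lsmeans: dict
    ses: dict
    ms_within: float


def fit_glm(bv: np.ndarray, genotype: Sequence[str]) -> GlmFit:
    """One-way fixed-effect ANOVA of breeding values on genotype class.

    F = MS_between / MS_within on (k-1, n-k) degrees of freedom; the LS mean
    of each class is its mean, with SE sqrt(MS_within / n_class). Degenerate
    inputs (fewer than 2 classes, or any class with fewer than 2 animals)
    raise :class:`DegenerateFitError`.
    """
    bv = np.asarray(bv, dtype=float)
    genotype = np.asarray(genotype)
    if bv.shape != genotype.shape:
        raise ValueError("bv and genotype must align")
    if np.isnan(bv).any():
        raise ValueError("bv must be non-missing for all used animals")
    classes = sorted(set(genotype.tolist()))
    k = len(classes)
    n = len(bv)
    if k < 2:
        raise DegenerateFitError(f"need >=2 genotype classes, got {k}")
    groups = {g: bv[genotype == g] for g in classes}
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise DegenerateFitError(f"class(es) with <2 animals: {small}")
    grand = bv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        f = 0.0 if ms_between == 0.0 else np.inf
        p = 1.0 if ms_between == 0.0 else 0.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_b, df_w))
    lsmeans = {g: float(v.mean()) for g, v in groups.items()}
    ses = {g: float(np.sqrt(ms_within / len(v))) for g, v in groups.items()}
    return GlmFit(
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        n_used=n,
        lsmeans=lsmeans,
        ses=ses,
        ms_within=float(ms_within),
    )


@dataclass
class AssociationResult:
    """One (SNP, trait) row of the association table."""

    snp_id: str
    trait: str
    status: str = "ok"  # "ok" or "skipped"
    reason: Optional[str] = None
    n_used: int = 0
    genotype_counts: dict = field(default_factory=dict)
    excluded_genotypes: list = field(default_factory=list)
    f_statistic: Optional[float] = None
    p_value: Optional[float] = None
    p_bonferroni: Optional[float] = None
    lsmeans: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    significant: Optional[bool] = None


def associate_all(
    pop: PopulationData,
    snp_ids: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    freq_threshold: float = 0.10,
) -> list[AssociationResult]:
    """Fit every (SNP, trait) pair: frequencies → rare-class exclusion → GLM.

    Animals carrying an excluded genotype, or missing the trait's breeding
    value, are dropped from that fit only. SNPs where fewer than two classes
    remain (or a remaining class has fewer than two animals) yield a row with
    ``status='skipped'`` and a reason; the batch never aborts. Results are
    sorted by SNP then trait. Significance uses the uncorrected p-value
    against *alpha*; a Bonferroni-adjusted p over the number of attempted
    fits is attached for information.
    """
    if snp_ids is None:
        snp_ids = pop.snp_ids
    results: list[AssociationResult] = []
    for snp in snp_ids:
        try:
            freqs = genotype_frequencies(pop, snp)
        except AllMissingError as exc:
            for trait in TRAITS:
                results.append(
                    AssociationResult(snp_id=snp, trait=trait, status="skipped", reason=str(exc))
                )
            continue
        retained, excluded = exclude_rare_genotypes(freqs, freq_threshold)
        # drop classes with zero animals from "retained" bookkeeping
        retained = [g for g in retained if freqs.counts[g] > 0]
        col = pop.genotypes[snp]
        keep_mask = col.isin(retained)
        for trait in TRAITS:
            base = AssociationResult(
                snp_id=snp,
                trait=trait,
                genotype_counts=dict(freqs.counts),
                excluded_genotypes=list(excluded),
            )
            if len(retained) < 2:
                base.status = "skipped"
                base.reason = f"<2 genotype classes retained at {snp}"
                logger.info("skipping %s/%s: %s", snp, trait, base.reason)
                results.append(base)
                continue
            bv = pop.bvs[trait]
            mask = keep_mask & bv.notna()
            try:
                fit = fit_glm(bv[mask].to_numpy(), col[mask].to_numpy())
            except DegenerateFitError as exc:
                base.status = "skipped"
                base.reason = str(exc)
                logger.info("skipping %s/%s: %s", snp, trait, base.reason)
                results.append(base)
                continue
            base.n_used = fit.n_used
            base.f_statistic = fit.f_statistic
            base.p_value = fit.p_value
            base.lsmeans = fit.lsmeans
            base.ses = fit.ses
            base.significant = fit.p_value < alpha
            results.append(base)
    n_tests = sum(r.status == "ok" for r in results)
    for r in results:
        if r.status == "ok":
            r.p_bonferroni = min(1.0, r.p_value * n_tests)
    results.sort(key=lambda r: (r.snp_id, TRAITS.index(r.trait)))
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into a tidy DataFrame (one row per SNP × trait)."""
    rows = []
    for r in results:
        total = sum(r.genotype_counts.values()) or 1
        geno_cols = {
            f"genotype_{g}": f"{r.genotype_counts.get(g, 0)}"
                             f"({r.genotype_counts.get(g, 0) / total:.2f})"
            for g in GENOTYPE_CODES
        }
        rows.append(
            {
                "snp_id": r.snp_id,
                "trait": r.trait,
                "status": r.status,
                "reason": r.reason,
                "n_used": r.n_used,
                **geno_cols,
                "excluded_genotypes": ",".join(r.excluded_genotypes),
                "f_statistic": r.f_statistic,
                "p_value": r.p_value,
                "p_bonferroni": r.p_bonferroni,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def lsmeans_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Companion table: per-class LS mean ± SE for every fitted (SNP, trait)."""
    rows = []
    for r in results:
        if r.status != "ok":
            continue
        for g, m in r.lsmeans.items():
            rows.append(
                {"snp_id": r.snp_id, "trait": r.trait, "genotype": g,
                 "lsmean": m, "se": r.ses[g], "n": int((r.genotype_counts or {}).get(g, 0))}
            )
    return pd.DataFrame(rows)
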