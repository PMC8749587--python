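"""Packaged reference tables from the Hanwoo trio MAE study.

These are static copies of the study's published result tables, used for
report-format tests and in-table arithmetic checks: the 14-gene MAE profile
(gene identity, parental origin of the expressed allele, dbMAE/Geneimprint
catalogue status, and the tissue pattern stated for each gene) and the
six-gene association table over 203 Korean-proven bulls (genotype counts and
the traits each SNP was associated with).
"""

from __future__ import annotations

import pandas as pd

from .io import PopulationData, TRAITS
from .trio import GeneMAEProfile, MATERNAL, PATERNAL

#: Discovery funnel of the source study: SNPs called from parental
#: resequencing, SNPs assigned to gene coordinates, opposite-homozygote
#: (obligate-heterozygous) exonic SNPs, genes they fall in, SNPs with MAE in
#: at least one tissue, and the genes/chromosomes those span.
FUNNEL = {
    "total_snps": 5_898_127,
    "genic_snps": 96_139,
    "informative_snps": 3_801,
    "genes_evaluated": 1_569,
    "mae_snps": 20,
    "mae_genes": 14,
    "chromosomes": 12,
}

#: Molecular consequences of the 20 MAE SNPs.
MAE_SNP_CONSEQUENCES = {"missense": 8, "synonymous": 4, "utr3": 8}

# gene_id, symbol, expressed allele, dbMAE entry, Geneimprint entry,
# tissues with MAE ("" where only "two tissues" is known, not which two)
_TABLE1 = [
    ("ENSBTAG00000015066", "LANCL1", "maternal", "M", "", "muscle;fat;brain"),
    ("ENSBTAG00000011820", "DAPK2", "maternal", "M and H", "", "muscle"),
    ("ENSBTAG00000009962", "PDCL3", "paternal", "", "", "muscle"),
    ("ENSBTAG00000008527", "SRSF6", "maternal", "M", "", ""),
    ("ENSBTAG00000014653", "SPNS1", "paternal", "M and H", "", ""),
    ("ENSBTAG00000001412", "N6AMT1", "maternal", "", "", "fat"),
    ("ENSBTAG00000018424", "ACKR3", "maternal", "M", "", "fat"),
    ("ENSBTAG00000021282", "SGCE", "paternal", "M and H", "C, M, H, and P", "fat;brain"),
    ("ENSBTAG00000018401", "APLF", "paternal", "M and H", "", "fat"),
    ("ENSBTAG00000017468", "NUCB2", "maternal", "M", "", ""),
    ("ENSBTAG00000035744", "TRIM26", "paternal", "", "", ""),
    ("ENSBTAG00000017143", "PDIA4", "paternal", "M", "", "brain"),
    ("ENSBTAG00000001839", "OCIAD2", "paternal", "M", "", "brain"),
    ("ENSBTAG00000046101", "ZNF470", "maternal", "", "", "brain"),
]


def mae_gene_table() -> pd.DataFrame:
    """The published 14-gene MAE profile table."""
    return pd.DataFrame(
        _TABLE1,
        columns=["gene_id", "gene_symbol", "expressed_allele", "dbmae",
                 "geneimprint", "mae_tissues"],
    )


def mae_gene_profiles() -> list[GeneMAEProfile]:
    """The published table as :class:`GeneMAEProfile` objects.

    Tissue statuses are filled in where the study states them (the
    all-tissue gene and the tissue-specific genes); genes described only as
    MAE in two unspecified tissues carry an empty tissue map but keep their
    published overall origin.
    """
    profiles = []
    for gene_id, symbol, origin, _, _, tissues in _TABLE1:
        status = MATERNAL if origin == "maternal" else PATERNAL
        tissue_status = {t: status for t in tissues.split(";") if t}
        profiles.append(
            GeneMAEProfile(
                gene_id=gene_id,
                gene_symbol=symbol,
                tissue_status=tissue_status,
                overall_origin=status,
            )
        )
    return profiles


# gene, snp_ids, allele string(s), AA/AB/BB counts, excluded classes,
# associated traits with printed p-value strings
_TABLE2 = [
    ("N6AMT1", ["rs466790251"], ["G/A"], (124, 71, 8), ["BB"],
     {"WT12": "0.005", "CWT": "<0.001", "LEA": "<0.001"}),
    ("ACKR3", ["rs384940597"], ["T/C"], (122, 73, 8), ["BB"],
     {"WT12": "<0.001", "CWT": "0.018"}),
    ("PDIA4", ["rs109714759"], ["C/T"], (157, 45, 1), ["BB"],
     {"WT12": "<0.001", "CWT": "0.003", "LEA": "0.005"}),
    ("PDCL3", ["rs133723669"], ["T/C"], (124, 71, 8), ["BB"],
     {"WT12": "0.030", "CWT": "0.042", "LEA": "<0.001"}),
    ("APLF", ["rs136662956", "rs133791032", "rs135512132"],
     ["A/G", "G/A", "C/T"], (80, 97, 26), [],
     {"CWT": "0.049"}),
    ("SPNS1", ["rs134811009"], ["A/G"], (182, 21, 0), ["BB"],
     {"LEA": "0.004", "MAR": "0.027"}),
]


def association_table() -> pd.DataFrame:
    """The published association table (one row per gene; APLF's three SNPs
    are completely linked and share one genotype column)."""
    rows = []
    for gene, snps, alleles, counts, excluded, traits in _TABLE2:
        rows.append(
            {
                "gene_symbol": gene,
                "snp_ids": ";".join(snps),
                "alleles": ";".join(alleles),
                "n_AA": counts[0],
                "n_AB": counts[1],
                "n_BB": counts[2],
                "excluded_genotypes": ";".join(excluded),
                "associated_traits": ";".join(f"{t}({p})" for t, p in traits.items()),
            }
        )
    return pd.DataFrame(rows)


def population_from_counts(snp_id: str, n_aa: int, n_ab: int, n_bb: int) -> PopulationData:
    """Expand published genotype counts into a single-SNP population.

    Breeding values are filled with zeros: the object supports genotype
    frequency/exclusion arithmetic, not refitting the published models (the
    study's breeding values were never released).
    """
    codes = ["AA"] * n_aa + ["AB"] * n_ab + ["BB"] * n_bb
    idx = pd.Index([f"KPN{i:04d}" for i in range(len(codes))], name="animal_id")
    geno = pd.DataFrame({snp_id: codes}, index=idx)
    bvs = pd.DataFrame(0.0, index=idx, columns=list(TRAITS))
    return PopulationData(genotypes=geno, bvs=bvs)
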