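"""Readers and writers for the file formats the pipeline touches.

VCF is handled through :mod:`pysam`; annotation, genotype-matrix and
breeding-value tables are plain tab-delimited files read with pandas.
All coordinates are 1-based, as in VCF itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Site-level INFO metrics the hard filter knows about.
METRIC_NAMES = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: The fixed consequence vocabulary. Sites absent from an annotation are
#: implicitly ``non_exonic``.
CONSEQUENCES = ("missense", "synonymous", "utr3", "utr5", "other_exonic", "non_exonic")

#: Mapping from snpEff ANN effect terms onto the consequence vocabulary.
#: Effects not listed here are treated as non-exonic.
SNPEFF_EFFECT_MAP = {
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "start_retained_variant": "synonymous",
    "3_prime_UTR_variant": "utr3",
    "5_prime_UTR_variant": "utr5",
    "5_prime_UTR_premature_start_codon_gain_variant": "utr5",
    "stop_gained": "other_exonic",
    "stop_lost": "other_exonic",
    "start_lost": "other_exonic",
    "initiator_codon_variant": "other_exonic",
    "coding_sequence_variant": "other_exonic",
}

#: The five routinely evaluated breeding-value traits: weight at 12 months,
#: carcass weight, loin eye area, backfat thickness, marbling score.
TRAITS = ("WT12", "CWT", "LEA", "BFT", "MAR")

BASES = ("A", "C", "G", "T")


class MissingSampleError(KeyError):
    """A required sample is absent from a VCF header."""


class MalformedFileError(ValueError):
    """A file could not be parsed in the expected layout."""


class UnknownConsequenceError(ValueError):
    """An annotation row carries a consequence outside the fixed vocabulary."""


class UnsortedSitesError(ValueError):
    """Sites handed to ``write_vcf`` are not sorted by (chrom, pos)."""


class NoOverlapError(ValueError):
    """Genotype and breeding-value tables share no animals."""


def _f32(x: float) -> float:
    # htslib stores Float INFO fields in single precision; coercing here makes
    # write->read a true identity on the data model.
    return float(np.float32(x))


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one site.

    ``genotype`` is an unordered pair of bases drawn from {ref, alt}, stored
    sorted, or ``None`` when the GT field is missing. Phase separators are
    ignored: parental origin is derived from parental homozygosity, never
    from the GT field.
    """

    genotype: Optional[tuple[str, str]]
    gq: int = 0
    dp: int = 0
    ad: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.genotype is not None:
            object.__setattr__(self, "genotype", tuple(sorted(self.genotype)))
        if self.gq < 0 or self.dp < 0:
            raise ValueError("GQ and DP must be non-negative")
        if self.ad is not None and sum(self.ad) > self.dp:
            raise ValueError("AD counts exceed DP")

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_hom(self) -> bool:
        return self.genotype is not None and self.genotype[0] == self.genotype[1]

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]

    @property
    def hom_allele(self) -> str:
        if not self.is_hom:
            raise ValueError("call is not homozygous")
        return self.genotype[0]


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP with its filter metrics and per-sample calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    snp_id: Optional[str] = None
    metrics: Mapping[str, float] = field(default_factory=dict)
    calls: Mapping[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError(f"not a biallelic SNP: {self.ref}>{self.alt}")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metric(s): {sorted(unknown)}")
        object.__setattr__(self, "metrics", {k: _f32(v) for k, v in self.metrics.items()})
        object.__setattr__(self, "calls", dict(self.calls))

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref, self.alt)

    def call(self, sample: str) -> Optional[SampleCall]:
        return self.calls.get(sample)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene assignment and molecular consequence of one SNP."""

    gene_id: str
    gene_symbol: str
    consequence: str

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise UnknownConsequenceError(
                f"consequence {self.consequence!r} not in {CONSEQUENCES}"
            )


@dataclass
class VcfReadResult:
    """Sites retained by ``read_vcf`` plus counts of what was dropped."""

    sites: list[VariantSite]
    n_multiallelic: int = 0
    n_indel: int = 0
    n_missing_sample: int = 0

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)


def _genotype_from_gt(gt, alleles: tuple[str, str]) -> Optional[tuple[str, str]]:
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        return None
    return tuple(sorted(alleles[i] for i in gt))


def read_vcf(path, required_samples: Optional[Iterable[str]] = None) -> VcfReadResult:
    """Read a VCF into :class:`VariantSite` records.

    Only biallelic SNPs are kept; multi-allelic and indel records are dropped
    and counted. INFO metrics outside the five the pipeline uses are ignored.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    MissingSampleError
        if any of *required_samples* is absent from the header.
    MalformedFileError
        if pysam cannot parse the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # pragma: no cover - htslib message varies
        raise MalformedFileError(f"cannot parse VCF {path}: {exc}") from exc

    header_samples = list(vf.header.samples)
    required = list(required_samples or [])
    missing = [s for s in required if s not in header_samples]
    if missing:
        raise MissingSampleError(f"sample(s) {missing} absent from {path}")

    res = VcfReadResult(sites=[])
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            res.n_multiallelic += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or set(ref + alt) - set(BASES):
            res.n_indel += 1
            continue
        metrics = {}
        for m in METRIC_NAMES:
            if m in rec.info:
                v = rec.info[m]
                metrics[m] = float(v[0] if isinstance(v, tuple) else v)
        calls = {}
        dropped_sample = False
        for name, sc in rec.samples.items():
            if required and name not in required:
                continue
            gt = sc.get("GT")
            genotype = _genotype_from_gt(gt, (ref, alt))
            gq = sc.get("GQ")
            dp = sc.get("DP")
            ad = sc.get("AD")
            if gt is None and gq is None and dp is None:
                dropped_sample = True
                continue
            calls[name] = SampleCall(
                genotype=genotype,
                gq=int(gq) if gq is not None else 0,
                dp=int(dp) if dp is not None else 0,
                ad=tuple(int(a) for a in ad[:2]) if ad is not None and ad[0] is not None else None,
            )
        if required and not set(required) <= set(calls):
            res.n_missing_sample += 1
            if dropped_sample:
                logger.debug("record %s:%s lacks data for a required sample", rec.chrom, rec.pos)
            continue
        res.sites.append(
            VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                snp_id=rec.id,
                metrics=metrics,
                calls=calls,
            )
        )
    vf.close()
    if res.n_multiallelic or res.n_indel or res.n_missing_sample:
        logger.info(
            "read_vcf(%s): dropped %d multiallelic, %d indel, %d missing-sample records",
            path, res.n_multiallelic, res.n_indel, res.n_missing_sample,
        )
    return res


def _build_header(sites: list[VariantSite]) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    seen = []
    for s in sites:
        if s.chrom not in seen:
            seen.append(s.chrom)
    for c in seen:
        hdr.add_line(f"##contig=<ID={c}>")
    for m in METRIC_NAMES:
        hdr.add_line(f'##INFO=<ID={m},Number=1,Type=Float,Description="{m}">')
    hdr.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    hdr.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    hdr.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    hdr.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    samples: list[str] = []
    for s in sites:
        for name in s.calls:
            if name not in samples:
                samples.append(name)
    hdr.add_samples(samples)
    return hdr


def write_vcf(sites: list[VariantSite], path) -> None:
    """Write sites as VCF v4.2, losslessly for the fields the model carries.

    Sites must already be sorted by (chrom, pos); chromosome order follows
    first appearance.
    """
    order = {}
    for s in sites:
        order.setdefault(s.chrom, len(order))
    keys = [(order[s.chrom], s.pos) for s in sites]
    if keys != sorted(keys):
        raise UnsortedSitesError("sites must be sorted by (chrom, pos)")

    hdr = _build_header(sites)
    vf = pysam.VariantFile(str(path), "w", header=hdr)
    sample_names = list(hdr.samples)
    for s in sites:
        rec = vf.new_record(contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt))
        rec.id = s.snp_id
        for m, v in s.metrics.items():
            rec.info[m] = v
        for name in sample_names:
            call = s.calls.get(name)
            sc = rec.samples[name]
            if call is None:
                sc["GT"] = (None, None)
                continue
            if call.genotype is None:
                sc["GT"] = (None, None)
            else:
                idx = {s.ref: 0, s.alt: 1}
                sc["GT"] = tuple(sorted(idx[a] for a in call.genotype))
            sc["GQ"] = call.gq
            sc["DP"] = call.dp
            if call.ad is not None:
                sc["AD"] = call.ad
        vf.write(rec)
    vf.close()


# ---------------------------------------------------------------------------
# annotation


def _read_annotation_tsv(path: Path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        return {}
    expected = ["chrom", "pos", "ref", "alt", "gene_id", "gene_symbol", "consequence"]
    if list(df.columns) != expected:
        raise MalformedFileError(
            f"annotation header must be {expected}, got {list(df.columns)}"
        )
    out: dict = {}
    for i, row in df.iterrows():
        if row["consequence"] not in CONSEQUENCES:
            raise UnknownConsequenceError(
                f"line {i + 2}: unknown consequence {row['consequence']!r}"
            )
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key in out:
            logger.warning("duplicate annotation for %s; first wins", key)
            continue
        out[key] = GeneAnnotation(row["gene_id"], row["gene_symbol"], row["consequence"])
    return out


def parse_ann_field(ann: str) -> Optional[GeneAnnotation]:
    """Map the first transcript of a snpEff ANN string onto the vocabulary."""
    first = ann.split(",")[0]
    fields = first.split("|")
    if len(fields) < 5:
        return None
    effect = fields[1]
    gene_symbol = fields[3]
    gene_id = fields[4]
    consequence = SNPEFF_EFFECT_MAP.get(effect.split("&")[0], "non_exonic")
    return GeneAnnotation(gene_id=gene_id, gene_symbol=gene_symbol, consequence=consequence)


def _read_annotation_vcf(path: Path) -> dict:
    vf = pysam.VariantFile(str(path))
    out: dict = {}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1 or "ANN" not in rec.info:
            continue
        ann = rec.info["ANN"]
        ann = ann[0] if isinstance(ann, tuple) else ann
        ga = parse_ann_field(str(ann))
        if ga is None:
            continue
        key = (rec.chrom, rec.pos, rec.ref, rec.alts[0])
        if key in out:
            logger.warning("duplicate annotation for %s; first wins", key)
            continue
        out[key] = ga
    vf.close()
    return out


def read_annotation(path) -> dict:
    """Read a SNP → gene/consequence map.

    Accepts either the tab-delimited layout
    ``chrom pos ref alt gene_id gene_symbol consequence`` (with that header)
    or a VCF whose ANN INFO subfield is parsed for the first transcript.
    Duplicate keys keep the first occurrence, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        return _read_annotation_vcf(path)
    return _read_annotation_tsv(path)


# ---------------------------------------------------------------------------
# population


GENOTYPE_CODES = ("AA", "AB", "BB")


@dataclass
class PopulationData:
    """Genotype matrix and breeding values over one bull population.

    ``genotypes``: animals × SNPs DataFrame of codes in {AA, AB, BB} with NaN
    for missing, B nominally the minor allele. ``bvs``: animals × the five
    traits. Both share the same animal index, in the same order.
    """

    genotypes: pd.DataFrame
    bvs: pd.DataFrame

    def __post_init__(self):
        if not self.genotypes.index.equals(self.bvs.index):
            raise ValueError("genotype and BV tables must share the animal index")
        missing = [t for t in TRAITS if t not in self.bvs.columns]
        if missing:
            raise MalformedFileError(f"BV table missing trait column(s): {missing}")
        self.bvs = self.bvs[list(TRAITS)]

    @property
    def animal_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_animals(self) -> int:
        return len(self.genotypes)


def read_population(genotype_path, bv_path) -> PopulationData:
    """Read genotype-matrix and breeding-value tables and align the animals.

    Animals present in only one of the two files are dropped with a warning;
    zero overlap is an error. Row order of the inputs is irrelevant: animals
    are sorted by id after alignment.
    """
    geno = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
    bvs = pd.read_csv(bv_path, sep="\t", index_col=0)
    geno.index = geno.index.astype(str)
    bvs.index = bvs.index.astype(str)
    missing = [t for t in TRAITS if t not in bvs.columns]
    if missing:
        raise MalformedFileError(f"BV table missing trait column(s): {missing}")
    common = sorted(set(geno.index) & set(bvs.index))
    if not common:
        raise NoOverlapError("no animals shared between genotype and BV tables")
    dropped = (set(geno.index) | set(bvs.index)) - set(common)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} animal(s) absent from one file")
    geno = geno.loc[common]
    bad = set(geno.stack().dropna().unique()) - set(GENOTYPE_CODES)
    if bad:
        raise MalformedFileError(f"unknown genotype code(s): {sorted(bad)}")
    return PopulationData(genotypes=geno, bvs=bvs.loc[common, list(TRAITS)])
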