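# Methods

## Model and assumptions

The pipeline infers parent-of-origin monoallelic expression (MAE) from a
single sire–dam–offspring trio. Its central assumption is that at a site
where the parents are homozygous for opposite alleles, the offspring is an
obligate heterozygote whose maternal and paternal alleles are identified
without phasing or offspring DNA evidence. MAE is then read directly off the
offspring's RNA genotype call in each tissue: a homozygous RNA call at an
obligately heterozygous site means one parental allele is silent. This is a
polymorphism-based screen, not a statistical test of allelic imbalance: a
single trio cannot distinguish genomic imprinting from random monoallelic
expression or cis-regulatory silencing (that would require reciprocal
crosses or many trios), and genes without informative exonic SNPs are
invisible to it.

## Filtering

Site-level hard filtering uses the standard five-metric recipe for SNPs:
a site fails when QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5 or
ReadPosRankSum < −8.0. All comparisons are strict — a value exactly at a
threshold passes — and an absent metric never fails, because the rank-sum
metrics are only defined at sites with heterozygous calls and failing on
absence would discard most homozygous parental records the trio logic needs.
Multi-allelic and indel records are dropped at read time with logged counts;
the screen is defined for biallelic SNPs only.

Per-call gates (GQ ≥ 20, DP ≥ 10, both inclusive) are applied separately in
two contexts: to the sire and dam DNA calls when selecting informative SNPs,
and to each RNA sample call when classifying expression. The offspring DNA
call is not required — offspring heterozygosity is inferred — but when
present and passing the gate, a non-heterozygous offspring call is treated
as a Mendelian violation and the site is excluded (on by default,
`mendelian_check: false` to disable).

## Expression classification and aggregation

The default classification uses the RNA genotype call (homozygous ⇒ MAE),
matching a workflow in which expression states come from a diploid caller
run on RNA-seq. Because a genotype call conflates low minor-allele
expression with its absence, an `allelic_fraction` mode is provided: with AD
counts available, a parental allele supported by ≥ 95% of reads
(configurable) is called as the expressed allele.

Aggregation is unanimity-over-callable at both levels. Within a tissue type
(two samples each), not-callable samples are dropped, one callable sample
suffices, and any disagreement between callable samples yields
`conflicting`, never MAE. The same rule combines the SNPs of a gene within a
tissue. A gene's overall origin is maternal (paternal) iff at least one
tissue shows that origin and none shows the opposite; both origins ⇒
`inconsistent`. `conflicting` and `not_callable` are first-class outputs,
reported but never counted as MAE. This rule is deliberately conservative
for MAE declaration while still permitting single-sample evidence; a
stricter both-samples-must-agree behaviour is obtained by treating
single-callable tissues as not callable downstream of the per-sample table
the pipeline writes.

## Association model

The genotype–breeding-value association is the one-way fixed-effect GLM
y_ij = μ + G_i + e_ij with no covariates (the responses are already
additive-genetic breeding values, so no environmental terms enter). With a
single fixed factor, all GLM sum-of-squares types coincide and the overall
genotype F test is the one-way ANOVA F = MS_between/MS_within on
(k−1, n−k) df; LS means equal class means with SE = sqrt(MS_within/n_class).
Genotype classes with frequency strictly below 0.10 are excluded per locus
(a class at exactly 0.10 is retained), the affected animals are dropped from
that SNP's fits only, and missing breeding values drop an animal from that
trait's fit only. LS means are computed over retained animals only — the
model never sees the excluded ones. No multiple-testing correction is
applied to the reported p-values; a Bonferroni-adjusted column over the
attempted fits is emitted for information. If the nominally minor B allele
is in fact the major one at a locus, AA/BB labels are swapped (logged) so
that B is always minor. Degenerate fits — fewer than two retained classes,
or a retained class with fewer than two animals, where within-class variance
is undefined — are skipped with a logged reason rather than aborting the
batch. When MS_within = 0: F = 0 and p = 1 if MS_between is also 0,
otherwise F = ∞ and p = 0.

## Synthetic data

The generator emulates the *post-calling* state of the study design, not
reads or alignment. Defaults (all overridable in `SimConfig`): 40 genes
with Poisson(3) SNPs each (≥ 1) on the 29 bovine autosomes at
non-overlapping coordinates; 30% of SNPs informative
(opposite-homozygote parents); 20% of genes imprinted, origin maternal with
probability 0.5, tissue patterns drawn as 1:2:3:3:5 over
all-tissues / muscle-only / fat-only / brain-only / two-tissues (the mix
reported for tissue-specific MAE in adult cattle tissues); exonic
consequences 8:4:8 over missense/synonymous/3'-UTR with 10% of SNPs
non-exonic; DNA depth Poisson(40), RNA depth Poisson(60); per-read base
error 0.001; 5% of sites violate exactly one hard-filter metric; and a
203-animal population at MAF 0.2 with unit trait SDs.

Read counts are binomial given the true allele fractions (1/0 for
homozygotes, 1/2 for heterozygotes, degenerate at the expressed allele for
imprinted gene × covered tissue), with per-read error flips. The caller
emulation calls a genotype homozygous when the minor-allele read fraction is
below 0.1 (configurable), and sets GQ to the phred-scaled likelihood gap
between the emitted genotype and the best alternative under a
binomial-error model (error floored at 1e-3 so GQ is finite at zero
simulated error; capped at 99). Each imprinted gene is guaranteed one
informative, exonic, filter-passing SNP so every planted MAE gene is
discoverable by construction; imprinted genes are always expressed, while
other genes can be dropped from the RNA VCFs at a configurable rate to
emulate unexpressed genes. Population genotypes are Hardy–Weinberg and
independent across SNPs; breeding values are purely additive (effect ×
B-allele count, in trait-SD units) plus independent normal noise — no
polygenic covariance, no linkage disequilibrium, no pedigree structure.

What passing tests show, therefore, is that the inference recovers planted
truth under the stated noise model, and degrades monotonically with base
error; they do not show robustness to alignment artefacts, allele-specific
mapping bias, RNA editing, or relatedness structure in the association
population, none of which the generator produces.

All randomness flows through one integer-seeded numpy PCG64 generator (the
RNA and population stages derive fixed offsets from the seed so stages can
be re-run independently); identical configurations produce byte-identical
output files. VCF INFO floats are single precision in htslib, so site
metrics are coerced through float32 on construction and emitted with ≤ 6
significant digits — write→read round trips are then exact.

## Numerical and design notes

- Genotypes are unordered; `/` and `|` separators read identically, since
  phase is derived from parental homozygosity, never from the GT field.
- Absent INFO metrics are represented as absent, never imputed to 0.
- The snpEff ANN → consequence mapping is a shipped table over six labels
  (missense, synonymous, utr3, utr5, other_exonic, non_exonic); effects not
  in the table are treated as non-exonic; the first transcript's effect is
  used. Duplicate annotation keys keep the first occurrence with a warning.
- The pipeline starts from VCFs; read trimming, alignment and variant
  calling are upstream dependencies, consumed not invoked. Annotations are
  likewise consumed, never computed.
- Problem sizes in the shipped analyses and acceptance checks (40 genes /
  120 SNPs, 400 SNPs × 5 traits for calibration) were chosen as the smallest
  sets at which every planted structure is represented several times over;
  all scale linearly via `SimConfig`.
- Reports are plain TSV plus a JSON manifest with stage-scoped counters, so
  the discovery funnel (total → hard-filtered → exonic → informative → MAE)
  is a first-class, diffable output.

## Packaged reference tables

`triomae.fixtures` ships static copies of the published result tables of the
Hanwoo trio study this pipeline operationalises: the 14-gene MAE profile
(origin, dbMAE/Geneimprint status, stated tissue patterns) and the six-gene
association table over 203 Korean-proven bulls (genotype counts, excluded
classes, associated traits). Genes described only as "MAE in two tissues"
without naming them carry an empty tissue map and their published overall
origin. The published breeding values themselves were never released, so the
fixture populations support genotype-frequency and exclusion arithmetic, not
refits of the published models. The published text lists one SNP id for
PDCL3 in prose that differs from its association-table entry
(rs109714759 vs rs133723669); the fixture follows the table and the
discrepancy is noted here, not resolved.

## Known limitations

Single trio ⇒ no control of random monoallelic expression; genotype-mode
classification is blind to partial allelic imbalance; the unanimity rule
can be defeated by one noisy sample (yielding `conflicting`); association
assumes independent animals and ignores relatedness among bulls; and the
generator's independence assumptions (no LD, no polygenic covariance) make
its power estimates optimistic relative to real populations.
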