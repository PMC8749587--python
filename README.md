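# triomae

Trio-based discovery of monoallelically expressed (MAE) genes from DNA and
RNA variant calls, with downstream association of MAE SNP genotypes against
estimated breeding values. The package implements the analysis used to
screen genomic imprinting in Hanwoo (Korean native cattle): whole-genome
variant calls for a sire and dam, RNA-seq variant calls for six tissue
samples (muscle, fat, brain — two each) of their offspring, and a genotyped
bull population with breeding values for five selection traits.

## The method

**Informative SNPs.** At a biallelic SNP where the sire is homozygous for
one allele and the dam homozygous for the other, the offspring is an
obligate heterozygote and the parental origin of each of its alleles is
known without phasing: the dam's allele is maternal, the sire's paternal.
Candidate sites must first survive the standard GATK-style hard filter
(fail when QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5 or
ReadPosRankSum < −8.0; absent metrics never fail), lie in an exon per the
supplied snpEff-style annotation, and both parental calls must pass
GQ ≥ 20 and DP ≥ 10.

**Expressed-allele classification.** At each informative SNP, the
offspring's RNA call in each tissue sample (again gated at GQ ≥ 20,
DP ≥ 10) is classified: homozygous for the maternal (paternal) allele ⇒
maternal (paternal) monoallelic expression; heterozygous ⇒ biallelic. An
alternative allelic-fraction mode calls MAE when ≥ 95% of AD reads support
one parental allele. The two samples of a tissue are combined by unanimity
over callable samples; SNP calls roll up to a gene × tissue profile, and a
gene's overall origin is maternal/paternal when at least one tissue shows
that origin and none shows the opposite.

**Association.** MAE SNP genotypes are tested against breeding values for
WT12 (weight at 12 months), CWT (carcass weight), LEA (loin eye area), BFT
(backfat thickness) and MAR (marbling) with the one-way fixed-effect GLM

    y_ij = μ + G_i + e_ij

where y_ij is the breeding value, μ the general mean, G_i the fixed effect
of genotype i and e_ij the random error. Genotype classes with frequency
strictly below 10% are excluded per locus; results are reported as the
overall genotype F test with least-square means ± SE per class, with
significance at p < 0.05 (uncorrected, Bonferroni column for information).

Because the study's raw sequencing data are not public, the package ships a
synthetic-data generator (`triomae.simulate`) that emulates the post-calling
state of such a study — planted imprinting states per gene and tissue,
Poisson read depths, per-read base errors, a naive diploid-caller emulation,
and a 203-animal Hardy–Weinberg population with planted additive SNP
effects — together with the ground-truth tables that every recovery test
consumes.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(outputs under `results/`, intermediate data under `scratch/`):

```bash
python analysis/01_simulate_study.py
python analysis/02_call_mae.py
python analysis/03_associate_bvs.py
python analysis/04_reference_tables.py
```

`01` simulates 40 genes / 120 SNPs with 8 planted MAE genes (4 maternal,
4 paternal) and audits the bundle's self-consistency. `02` runs the pipeline
and prints the discovery funnel and the recovered gene × tissue matrix:

```
discovery funnel:
  total_sites: 120
  hard_filter_pass: 117
  exonic: 108
  informative: 43
  mae_snps: 13
  mae_genes: 8
recovered 8/8 planted MAE genes (origin + tissue pattern); 0 false MAE genes
  gene_id gene_symbol  chrom    muscle       fat     brain overall_origin
SYNG00001          G1      2 biallelic  paternal biallelic       paternal
SYNG00004          G4      5  maternal biallelic biallelic       maternal
...
```

Each funnel line counts the sites surviving a stage: 120 called SNPs, 117
after the hard filter, 108 exonic, 43 with opposite-homozygote parents, 13
showing MAE in at least one tissue, in 8 genes — all 8 matching the planted
truth in both parental origin and tissue pattern, with no false positives.

`03` plants a 0.8 trait-SD additive effect on WT12 at one MAE SNP in a
simulated 203-bull population and recovers it:

```
tested 13 MAE SNPs x 5 traits: 65 fits, 4 significant at p < 0.05
planted effect: 0.8 SD on WT12 at ssnp00001
   snp_id trait  n_used  f_statistic  p_value
ssnp00001  WT12     197    16.441159 0.000072
...
```

The planted SNP is by far the strongest signal (p = 7.2e-5); the remaining
three nominal hits across 64 null fits are consistent with the 5% false-positive
rate of uncorrected testing.

The same pipeline is scriptable via the `triomae` CLI (`simulate`, `run`,
`associate`) driven by a YAML config, and as a library
(`triomae.run_pipeline`).

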