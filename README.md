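# admixscan

Admixture-mapping analysis toolkit for three-way admixed cohorts
(Native American / European / African), built around a fully seeded
synthetic-cohort generator so every stage is testable without external
genotype data.

## What it does

- **Synthetic cohorts** (`admixscan.synthetic`): single-pulse admixture
  model — haploid ancestry paths with Poisson crossovers and i.i.d.
  ancestry redraws, evaluated at marker positions into 0/1/2 NAM copy
  counts; ancestry-conditional Bernoulli genotypes; a triglyceride-like
  trait with sex/age/age²/BMI covariate structure, a planted per-allele
  causal effect, and an invertible medication effect. One master seed,
  independent named substreams.
- **Phenotype preparation** (`admixscan.phenotype`): medication
  adjustment (configurable additive/multiplicative rules), OLS covariate
  residualization, and the Blom rank-based inverse-normal transform
  (Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties).
- **Ancestry model** (`admixscan.ancestry`): local-ancestry matrices,
  global ancestry as the per-individual mean of local copies, and the
  top-vs-bottom trait-quartile NAM ancestry contrast profile.
- **Admixture scan** (`admixscan.scan`): per-marker OLS of the
  transformed trait on NAM locus ancestry with global-ancestry and
  diabetes covariates; label-swapping **Max(T) permutation** family-wise
  error control with (k+1)/(B+1) empirical p-values; conditional scans
  with genotype-dosage covariates.
- **Genotype association & meta-analysis** (`admixscan.assoc`):
  additive-dosage OLS scans and inverse-variance fixed-effects
  meta-analysis with allele harmonization.
- **Fine mapping** (`admixscan.finemap`): Wakefield-style approximate
  Bayes factors (log-space, stable to |z| ≥ 40), normalized posteriors,
  and 99% credible sets; prior effect variance ω = 0.04 by default, two
  ABF prefactor forms behind a flag.
- **Parental frequency** (`admixscan.parental`): extrapolation of an
  unobserved parental allele frequency from the admixed cohort
  frequency, reference frequencies, and admixture proportions, with a
  delta-method standard error and an ancestry-stratified cross-check.
- **IO & QC** (`admixscan.io`, `admixscan.qc`): TSV matrices with
  sidecar marker maps, RFMix-style per-haplotype call files, minimal
  VCF write / cyvcf2-backed read, YAML run configs, and marker QC
  (MAF ≥ 1%, exact Hardy–Weinberg test in controls, per-group
  missingness ≤ 5%, strand-ambiguous A/T–C/G removal).

## CLI

```bash
admixscan simulate --n 2000 --markers 150 --seed 1 --out cohort/
admixscan prep     --bundle cohort/ --trait TG --out prepared.tsv
admixscan scan     --bundle cohort/ --trait TG --permutations 10000 --seed 1 --out scan.tsv
admixscan scan     --bundle cohort/ --condition-on m00075 --seed 1 --out scan_cond.tsv
admixscan contrast --bundle cohort/ --trait TG --out contrast.tsv
admixscan assoc    --bundle cohort/ --trait TG --out stats.tsv
admixscan meta     --stats stats1.tsv --stats stats2.tsv --out meta.tsv
admixscan credset  --stats meta.tsv --omega 0.04 --mass 0.99 --out credset.tsv
admixscan parental-freq --p-adm 0.38 --props 0.6486,0.3190,0.0324 --p-eur 0.12 --p-afr 0.20 --n 1787
admixscan qc       --bundle cohort/ --out qc_report.tsv
```

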