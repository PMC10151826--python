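# genosleep

Analysis toolkit linking genotype to body-weight/sleep-style phenotypes, built
around five pillars and a synthetic-data layer with known ground truth:

- **`genosleep.synthetic_data`** — simulators for Hardy–Weinberg genotype
  matrices, exposure/outcome cohorts with a configurable latent confounder and
  per-SNP direct (pleiotropic) effects, two-sample GWAS summary statistics,
  per-fly 30-s binned activity records with circadian structure and optional
  death times, and small assay fixture tables. Every generator is a pure
  function of (parameters, seed).
- **`genosleep.association`** — per-SNP covariate-adjusted OLS scans
  (`phenotype ~ intercept + dosage + covariates`) with Benjamini–Hochberg FDR
  within the scan; monomorphic variants are flagged and excluded from the FDR
  family rather than dropped.
- **`genosleep.mr`** — Mendelian randomisation from summary statistics:
  allele harmonization (strand-flip resolution, ambiguous-palindrome
  dropping at folded EAF > 0.42), Wald ratio, fixed/random-effect
  inverse-variance weighting, and the weighted median with a seeded
  parametric-bootstrap SE.
- **`genosleep.dam`** — activity-monitor file parsing (42-column
  tab-delimited dialect, 32 channels), sleep scoring as maximal zero-count
  runs of ≥ 5 min starting at the first lights-on, waking activity,
  autocorrelation-based rhythmicity exclusion, last-waking-bout death
  calling and starvation survival tables.
- **`genosleep.assays`** — counter-current climbing index, CAFE capillary
  intake, comparative-Ct (ΔΔCt) fold changes with a replicate-CV exclusion
  rule (default 3%), and per-reference normalization.
- **`genosleep.survival`** — Kaplan–Meier product-limit curves with
  Greenwood variance and the two-group Mantel–Haenszel log-rank test.

## CLI

One entry point with subcommands:

```sh
genosleep simulate cohort --n-individuals 5000 --n-snps 20 --seed 1 --out-prefix cohort
genosleep simulate activity --n-flies 16 --days 7 --seed 1 --out Monitor1.txt
genosleep simulate fixtures --kind qpcr --out plate.csv

genosleep scan --genotypes cohort.genotypes.tsv --phenotypes cohort.phenotypes.tsv \
               --phenotype outcome --covariates age,sex --q 0.05 --out scan.tsv
genosleep mr --exposure expo.tsv --outcome outc.tsv --methods wald,ivw,wmedian --seed 7
genosleep sleep score Monitor1.txt --lights-on 08:00 --days 7 --min-sleep-min 5
genosleep survival km surv.tsv
genosleep survival logrank surv.tsv --group-col group
genosleep assay climbing climb.csv
```

Summary-statistic TSVs carry `variant_id, effect_allele, other_allele, eaf,
beta, se, pval, n`; survival TSVs carry `subject_id, time, event, group`.

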