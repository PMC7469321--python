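# methbp

Targeted-bisulfite DNA-methylation / blood-pressure association pipeline:
per-CpG quantification with QC, covariate-adjusted single-CpG regression per
5% methylation, Benjamini–Hochberg FDR, gene-based tests (average methylation
and the weighted truncated product method with a permutation null), and
DerSimonian–Laird random-effects meta-analysis across two samples. A
synthetic-cohort generator makes every stage testable without any external
data download.

## Layout

| module | what it does |
| --- | --- |
| `methbp.simulate` | synthetic cohorts: covariates, correlated CpG methylation (latent Gaussian copula), SBP/DBP/hypertension, read counts |
| `methbp.quant` | Bismark-coverage parsing, conversion-rate and coverage QC, methylation matrix, GRCh37/TSS coordinate bookkeeping |
| `methbp.association` | per-5% linear (SBP/DBP) and logistic (hypertension) models, pooled t test from moments, 2×2 chi-square, phenotype helpers |
| `methbp.multiple_testing` | BH step-up q-values |
| `methbp.gene_based` | average-methylation test, (w)TPM statistics, closed-form independent null, Freedman–Lane permutation null |
| `methbp.meta` | fixed-effect and DerSimonian–Laird pooling with Q, τ², I² |
| `methbp.pipeline` / `methbp.cli` | YAML-config-driven end-to-end driver |
| `methbp.datasets` | bundled NPPA promoter panel and published summary statistics |

## CLI

All subcommands take a single YAML config (see
`src/methbp/data/demo_config.yaml`) plus optional `--outdir` / `--seed`
overrides; exit code 2 signals a config validation error.

```sh
methbp all      --config src/methbp/data/demo_config.yaml --outdir out
methbp simulate --config src/methbp/data/demo_config.yaml --outdir sim
methbp qc       --config my_inputs.yaml        # coverage files -> matrix + QC report
methbp meta out1/association_sbp.tsv out2/association_sbp.tsv --out meta.tsv
```

`all` writes: `qc_report.tsv`, `methylation_matrix.tsv`,
`group_comparison.tsv` (group means ± SD, pooled t-test p, BH q),
`association_{sbp,dbp,hypertension}.tsv` (β per 5%, SE, p, q, OR + CI),
and `gene_based.tsv` (average + wTPM, permutation p, B, seed). Reruns with
the same config are bit-identical.

## Notes

- QC boundaries follow the stated removal rules: conversion rate < 0.98
  drops a sample, mean coverage < 20× drops a site (boundary values kept).
- The permutation null for wTPM uses Freedman–Lane for continuous outcomes
  and joint row-permutation of covariate-residualized methylation for the
  binary outcome; the closed-form independent-case TPM null is retained as
  an oracle (`gene_based.tpm_pvalue_independent`).
- p-values censored as “< 0.001” in the bundled reference tables are
  represented by 0.0005; every consumer is invariant to the exact
  placeholder below 0.001.
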