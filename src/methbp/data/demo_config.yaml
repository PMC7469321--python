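# Demo pipeline configuration: simulate a small cohort with effect sizes
# on the scale of the bundled reference panel and run every stage.
seed: 20200903
outdir: methbp_demo_out
tau: 0.1
B: 499
qc:
  conversion_threshold: 0.98
  min_mean_coverage: 20
simulate:
  n_samples: 800
  beta_sbp_per5: [-1.0, 0.3, -0.3, 0.0, 0.1, -0.5, -0.2, -0.6, -0.2]
  beta_dbp_per5: [-0.4, 0.1, -0.2, -0.1, -0.1, -0.2, -0.2, -0.3, -0.2]
  cpg_corr_rho: 0.7
read_counts:
  mean_coverage: 200
  coverage_dispersion: 10
  conversion_rate: 0.995
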