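# Annotated pipeline configuration for `burdenmeta run --config ...`.
# Unknown keys are rejected; every field shown has the default noted.

seed: 42                      # master seed for every random draw

# Stages run in this fixed order; omit a stage to skip it. "meta" is
# opt-in and needs cohort_summaries below.
stages: [simulate, qc, ancestry, annotate, enrich, genetest]

# When "simulate" is absent, load a previously written cohort instead:
# cohort_dir: path/to/cohort
out_dir: burdenmeta_out       # all result tables land here

# SimulationConfig fields (only overrides need listing). Defaults mirror
# the reference study: 11,580/10,555 cases/controls, 161 panel genes with
# 80 constrained, planted constrained-gene PTV odds ratio 1.48.
simulation:
  n_cases: 1000
  n_controls: 1000
  n_genes: 40
  target_ptv_or: 1.5
  baseline_shift_or: 1.1
  n_qc_outliers: 5
  n_related_pairs: 3

# rare-variant definition: "mac" (minor allele count <= mac_max, the
# combined-analysis rule) or "maf" (minor allele frequency < maf_max,
# the within-ancestry rule)
rare_mode: mac
mac_max: 5
maf_max: 0.001

analysis_mode: combined       # or "stratified" (per-ancestry, 4 PCs, maf rule)

# Sample-QC thresholds may be overridden per metric, e.g.:
# qc_thresholds: {mean_depth_min: 35}
qc_thresholds: {}
kinship_flag: 0.0442          # third-degree kinship flagging bound

knn_k: 5                      # ancestry KNN neighbours
knn_components: 3             # PCs used for KNN
outlier_n_sd: 6.0             # within-ancestry PC outlier bound
outlier_max_rounds: 5
n_reference_per_pop: 100      # simulated reference panel size per population

alpha: 0.05
n_classes_tested: 5           # Bonferroni terms for the enrichment report
gene_test_n_tests: 161        # Bonferroni denominator for per-gene tests

# Gene-level summary TSVs (gene, p_value, direction + cohort, n_cases,
# n_controls, n_trios columns) to meta-analyze when the "meta" stage is on:
cohort_summaries: []
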