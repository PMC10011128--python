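"""Gene-set burden enrichment with Firth-penalized logistic regression.

Plants a rare-PTV enrichment (OR 1.5) in the constrained genes of a
synthetic cohort and recovers it: phenotype ~ PTV burden + 5 PCs + rare
synonymous baseline, rare = minor allele count <= 5.
"""

from burdenmeta import SimulationConfig, simulate_cohort
from burdenmeta.ancestry import compute_pcs
from burdenmeta.annotation import classify_variants
from burdenmeta.burden import global_enrichment_test

config = SimulationConfig(n_cases=5000, n_controls=5000, target_ptv_or=1.5,
                          n_common_snps=300, per_call_depth=False, seed=1)
cohort = simulate_cohort(config)
cohort.variants = classify_variants(cohort.variants)

common = cohort.variants.index[cohort.variants["class_true"] == "common_snp"]
pcs = compute_pcs(cohort.subset_variants(common).dosages,
                  cohort.sample_ids, n_components=5).scores

report = global_enrichment_test(cohort, pcs, variant_class="PTV")
row = report.iloc[0]
print(f"planted OR: {config.target_ptv_or}")
print(f"recovered OR: {row.odds_ratio:.2f} "
      f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f})")
print(f"penalized-LRT p: {row.p_value:.2e}  "
      f"(significant at 0.05/5: {bool(row.significant)})")
print(f"rare PTVs in the constrained gene set: {int(row.n_variants)}")
# The CI should cover the planted odds ratio; the Firth penalty keeps the
# estimate finite even when rare-allele counts are extremely sparse.
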