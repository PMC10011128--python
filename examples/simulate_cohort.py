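"""Generate a synthetic case-control sequencing cohort and inspect it.

The generator emulates a targeted gene-panel study: five continental
populations, constrained (pLI > 0.9) and unconstrained panel genes, rare
variants in each analysis class, and a case enrichment of rare PTVs
concentrated in the constrained genes at a chosen odds ratio.
"""

from burdenmeta import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_cases=1000, n_controls=1000, n_genes=40, constrained_fraction=0.5,
    target_ptv_or=1.5,       # planted case enrichment for constrained-gene PTVs
    baseline_shift_or=1.1,   # mild global excess across the other coding classes
    n_common_snps=200, seed=7,
)
cohort = simulate_cohort(config)

print(f"samples: {len(cohort.samples)} "
      f"({(cohort.samples.phenotype == 1).sum()} cases)")
print(f"variants: {len(cohort.variants)} across {len(cohort.panel)} panel genes")
print(f"constrained genes: {int(cohort.panel.constrained.sum())}")
print("population counts:")
print(cohort.samples.population.value_counts().to_string())
print(f"truth: planted OR = {cohort.truth.true_or} in "
      f"{len(cohort.truth.enriched_genes)} enriched genes")
# The dosage matrix is samples x variants with 0/1/2 alt-allele copies
# (-1 marks a no-call); downstream stages consume it through CohortBundle.
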