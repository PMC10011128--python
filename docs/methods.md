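# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limits of what the test suite demonstrates.

## Analysis model

The central quantity is a per-sample burden: the summed alternate-allele
dosage over rare variants of one class inside a gene set. Classes are
protein-truncating (stop gained, frameshift, essential splice
donor/acceptor), missense tiered by MPC (tier 1: MPC > 3; tier 2:
MPC ∈ [2, 3], closed interval; nondamaging: MPC < 2) and synonymous; a
variant with several annotations takes the most damaging one. Missense
variants without an MPC score are classed nondamaging and thereby excluded
from the damaging-missense analyses, mirroring the score's limited
transcript coverage; each such variant is logged. Rarity is judged on the
minor allele: count ≤ `mac_max` (default 5, closed bound) in combined
analyses, frequency < `maf_max` (default 0.001, strict bound) within
ancestry strata, where the relaxed definition preserves power in smaller
strata.

Enrichment is a Firth-penalized logistic regression of phenotype on the
burden, the leading ancestry principal components (five global, or four
within-ancestry in stratified mode) and a baseline rare-variant count. The
baseline pairing — synonymous baseline for PTV/missense burdens,
nonsynonymous baseline for the synonymous burden — keeps the covariate
informative about sample-level technical variation while minimally
overlapping the burden of interest. Stratified analyses pool PTVs with
tier-1 missense (their effects are comparable and both classes are
extremely sparse), test strata with at least 100 samples, and are meant to
be combined across cohorts by inverse-variance weighting.

### Firth fit

The penalized likelihood ℓ(β) + ½·log|I(β)| is maximized by Newton
iterations on the hat-diagonal-adjusted score
U\*ⱼ = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢⱼ with step-halving whenever a step
would decrease the penalized likelihood. Convergence requires every score
component below 1e-6, capped at 100 iterations; non-convergence flags the
result rather than failing silently. The default p-value is the penalized
likelihood-ratio test (refitting with the coefficient pinned at zero and
the full Jeffreys penalty retained), which is the sparse-data-robust
choice; Wald is available. Confidence intervals default to profile
penalized likelihood, found by bracketing plus Brent root-finding on the
profile deficit; Wald intervals are the fast option used inside large
Monte-Carlo loops, where the regression is well conditioned and the two
coincide. A covariate column with no variation (e.g. an all-zero baseline
count in a tiny cohort) is dropped with a log note; a constant *burden*
column makes the test undefined and yields a NaN report row instead of an
error, so a multi-class report never dies on its sparsest class. Genuinely
collinear designs raise an error naming the offending columns.

### Exact tests

The per-gene test is Fisher's exact test on [PTV, non-PTV] × [case,
control] allele counts, two-sided by the minimum-likelihood rule: the sum
of hypergeometric probabilities (fixed margins) of all tables whose point
probability is at most the observed one, with relative slack 1e-7 for
floating-point ties, computed in log space so margins in the tens of
thousands are exact to machine precision. The reported effect is the
cross-product odds ratio with conventions ∞ (events only in cases), 0
(only in controls) and NaN (no events). Pooling a gene subset sums PTV
counts; the default denominator is the per-gene mean total allele count,
since per-gene totals refer to (nearly) the same samples and summing them
would multiply the denominator by the subset size. The pooled OR/p is
descriptive and the pooling method is echoed on the result — a
covariate-adjusted regression is the better instrument when individual
data are available.

### Meta-analysis

Signed Stouffer uses zᵢ = dᵢ·Φ⁻¹(1 − pᵢ/2) (p = 1 maps to z = 0; p = 0 is
clamped to 1e-300 with a warning) and Z = Σwᵢzᵢ/√(Σwᵢ²). The study weight
w = 4/(1/n_cases + 1/n_controls) + n_trios is applied literally by
default; a `sqrt_weights` option applies √w instead, the conventional
sample-size weighting, since the two differ only when study sizes are
unequal and the evidence for one convention over the other is thin. Genes
absent from a cohort are combined over the cohorts that carry them (the
panel-versus-exome asymmetry). Inverse-variance combination of log odds
ratios is fixed-effect; no random-effects model is provided.

## Quality control

A no-call becomes homozygous reference when its read depth is strictly
greater than ten, otherwise stays missing. Sample exclusion applies nine
thresholds (MappedReads < 400,000; MeanDepth < 40; OnTarget < 80;
Uniformity < 65; MissingCallRate > 0.3; Inbreeding_F > 0.6;
Het_Hom_Ratio < 0.6; Total_SNPs < 400; Total_Indels < 10), every
comparison strict, each exclusion listing every violated criterion. The
site filter then drops variants with a missing-call fraction strictly
above 10%; the pipeline orders the stages no-call resolution → sample QC →
site filter, and missingness denominators use the samples present at the
stage where the filter runs. The case/control balance of exclusions is
checked by a Pearson chi-square with Yates continuity correction (the
uncorrected statistic is an option); on the reference counts
(55/12,045 vs 38/11,212) the corrected test gives p = 0.1878 and the
uncorrected 0.1553, which is why correction is the default. Relative
pairs (kinship ≥ 0.0442, the third-degree convention, configurable) are
pruned one member per pair by ordered rules — fewer relatives in the
cohort, case over control, has SNP-array data, has reported sex, lower
rare-variant missingness, then lexicographically smaller id — iterating in
sorted pair order until no flagged pair survives.

## Ancestry

Principal components are computed on LD-pruned common SNPs (MAF > 1%;
greedy pruning at r² ≤ 0.2 within a 50-variant trailing window, the
conventional defaults) from the standardized, mean-imputed dosage matrix.
The implementation eigendecomposes the variant cross-product when variants
are fewer than samples and uses SVD otherwise; both are exact, and a sign
convention (largest-magnitude loading positive) makes scores fully
deterministic. Cohort samples are placed by joint PCA with a labelled
reference panel (projection-only is not the default because joint PCA is
the simpler, more faithful procedure when the reference is simulated from
the same frequency model) and classified by K nearest neighbours (K = 5,
first three components, Euclidean distance); a tied plurality is resolved
by the single nearest neighbour's label. Within-population outliers are
removed iteratively: any sample more than `n_sd` = 6 standard deviations
from the mean on one of the top four components, recomputing components
each round, at most 5 rounds — "obvious outlier" is not a precise notion,
so both knobs are configuration.

## The synthetic cohort generator

The generator produces what the analysis assumes and nothing more.

* **Population structure.** Five super-populations with allele-frequency
  deviations on rank-3 ancestry coordinates (a triangular bipyramid of
  unit vectors), per-SNP deviation variance Fst·p(1−p) with Fst the
  `divergence` parameter (default 0.1). The rank-3 geometry mirrors real
  continental data, where the top three principal components separate the
  five super-populations — with a full-rank symmetric divergence model
  they provably cannot, which would make the three-component KNN
  classifier ill-posed. The default of 1,372 common SNPs matches the
  LD-pruned SNP count of the reference study.
* **Rare variants.** Per gene and class, counts set by
  `variants_per_gene_by_class`; base frequencies uniform on
  `rare_allele_freq_range` (default 1e-5 to 2e-4, so that observed minor
  allele counts mostly fall under the MAC ≤ 5 rule at the default cohort
  size), with per-population lognormal jitter (sd 0.3) and Hardy–Weinberg
  genotypes within population.
* **Disease model.** Prospectively logistic: intercept +
  log(`target_ptv_or`)·(enriched-gene PTV count) +
  log(`baseline_shift_or`)·(every other rare coding count). Cases and
  controls are sampled retrospectively by exact exponential tilting — a
  per-allele odds multiplication applied to each variant's frequency in
  cases — which reproduces that logistic model exactly for independent
  variants. Two consequences matter. First, recovery semantics are exact:
  the downstream regression's burden coefficient estimates
  log(`target_ptv_or`) with no approximation. Second, the baseline shift
  deliberately excludes the enriched-gene PTVs: it models a global excess
  (technical or biological) that the baseline covariate exists to absorb,
  and under this construction the PTV test with `target_ptv_or` = 1 is
  exactly null whatever the shift — the calibration property the test
  suite verifies. A shift that also tilted the enriched-gene PTVs would by
  construction be a real PTV effect, not a baseline artifact, and no
  covariate could (or should) remove it. Defaults: `target_ptv_or` = 1.48
  (the reference study's estimate), `baseline_shift_or` = 1.1 (the study
  reports a global excess without quantifying it; 1.1 is a modest value of
  the kind the baseline covariate is meant to soak up).
* **Depths and missingness.** Per-sample mean depth normal (60 ± 5,
  clipped at 44 so unplanted samples never breach the MeanDepth
  threshold), per-call Poisson; `per_call_depth=False` substitutes the
  per-sample constant for large Monte-Carlo loops, which is
  indistinguishable downstream because the only depth-dependent rule
  (no-call promotion at depth > 10) is essentially never triggered at
  mean depth 60. Missingness is uniform at `missing_rate` (default 2%).
* **QC metrics and outliers.** The nine metrics are drawn comfortably
  inside their thresholds (≥ 4 standard deviations); planted outliers get
  one randomly chosen metric redrawn strictly beyond its threshold, so
  QC recovery is exact by construction — which is the point: the tests
  close the loop between generator and filter, not between filter and
  messy reality.
* **Relatives.** Pairs are created by copying one member's genotypes to
  the other with per-site resampling at rate 1 − 2·kinship (duplicates
  kinship 0.5, first-degree 0.25); only the pair labels are consumed
  downstream.
* **Cohort summaries.** Gene-level fixtures for the meta layer: null
  genes draw z ~ N(0,1) (uniform two-sided p, random direction), shared
  signal genes z ~ N(3,1) with positive direction.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, admixed individuals, trio genotypes, sequencing-read
artifacts, batch-correlated genotyping error, or any dependence between
variants beyond population frequency. Passing tests therefore demonstrate
that the statistical machinery is correct under the stated model — not
that the pipeline is robust to every failure mode of real sequencing data.

## Problem sizes in the test suite

Monte-Carlo checks use the sizes at which the claims are stated: type-I
error over 500 fresh null cohorts of 2,000 samples; 95% CI coverage of a
planted odds ratio 1.5 over 100 cohorts of 10,000; baseline-shift
calibration over 500 cohorts of 2,000. These loops set
`n_common_snps` = 300, `per_call_depth` = False and `missing_rate` = 0:
the number of PCA SNPs, the depth model and uniform missingness do not
interact with the calibration or coverage of the burden regression, and
the reductions keep each replicate cheap. Ancestry accuracy is scored
under its stated conditions (500 reference, 1,000 cohort samples,
divergence 0.1, full 1,372-SNP default).

## Known limitations

* The exact per-gene test cannot adjust for covariates; the enrichment
  regression is the covariate-aware instrument.
* Profile-likelihood CIs assume a unimodal profile (true for the
  penalized logistic likelihood).
* Kinship estimation is upstream: the pruner consumes pairs, it does not
  infer them.
* The pooled gene-subset OR depends on the denominator convention; both
  conventions are reported mechanisms, neither is a substitute for a
  joint model.
* The Stouffer weight convention (w vs √w) changes results when study
  sizes are very unequal; both are exposed and the literal form is the
  default.
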