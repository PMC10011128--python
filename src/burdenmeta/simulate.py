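"""Synthetic case-control cohorts with the statistical structure the analysis assumes.

The generator emulates a targeted-panel sequencing study: five continental
super-populations with Balding-Nichols-divergent common-SNP frequencies
(giving PC-separable clusters), a gene panel in which a fraction of genes
is evolutionarily constrained (pLI > 0.9), rare variants in the analysis
classes (PTV, missense tiers, synonymous) at Hardy-Weinberg within each
population, per-call read depths and missingness, optional related sample
pairs, and per-sample QC metric distributions with plantable outliers.

Case enrichment uses exact exponential tilting: if the prospective disease
model is logistic in the summed rare-PTV count over the enriched (=
constrained) genes with per-allele odds ratio ``target_ptv_or``, then
retrospectively sampled cases carry each enriched-gene PTV allele at odds
multiplied by exactly that ratio, and controls at the population odds.
Sampling cases and controls that way makes the downstream logistic
regression coefficient for the summed count exactly log(target_ptv_or).
An optional ``baseline_shift_or`` tilts ALL rare coding classes in cases,
emulating a global technical/biological baseline excess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import MISSING, CohortBundle, TruthRecord
from .meta import CohortSummary
from .qc import METRIC_COLUMNS

SUPER_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

DEFAULT_MIX = {"AFR": 0.1, "AMR": 0.1, "EAS": 0.15, "EUR": 0.5, "SAS": 0.15}

DEFAULT_VARIANTS_PER_GENE = {
    "PTV": 3,
    "missense_tier1": 1,
    "missense_tier2": 2,
    "missense_nondamaging": 3,
    "synonymous": 4,
}

_CONSEQUENCE_FOR_CLASS = {
    "PTV": ("stop_gained", "frameshift_variant", "splice_acceptor_variant",
            "splice_donor_variant"),
    "missense_tier1": ("missense_variant",),
    "missense_tier2": ("missense_variant",),
    "missense_nondamaging": ("missense_variant",),
    "synonymous": ("synonymous_variant",),
}

#: rare coding classes subject to the global baseline shift
_CODING_CLASSES = tuple(DEFAULT_VARIANTS_PER_GENE)

#: unit-norm ancestry coordinates (triangular bipyramid): five well-separated
#: populations whose between-population structure is exactly rank 3
_POP_COORDS = {
    "AFR": (0.0, 0.0, 1.0),
    "EAS": (0.0, 0.0, -1.0),
    "EUR": (1.0, 0.0, 0.0),
    "SAS": (-0.5, np.sqrt(3) / 2, 0.0),
    "AMR": (-0.5, -np.sqrt(3) / 2, 0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative knobs for one synthetic cohort.

    Defaults mirror the reference study's design: 11,580 cases and 10,555
    controls over a 161-gene panel of which 80 genes (pLI > 0.9) carry the
    case enrichment at odds ratio 1.48, with a mild global baseline excess
    (odds ratio 1.1) across all rare coding classes.
    """

    n_cases: int = 11_580
    n_controls: int = 10_555
    population_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    n_genes: int = 161
    constrained_fraction: float = 80 / 161
    variants_per_gene_by_class: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANTS_PER_GENE))
    rare_allele_freq_range: tuple = (1e-5, 2e-4)
    target_ptv_or: float = 1.48
    baseline_shift_or: float = 1.1
    depth_mean: float = 60.0
    depth_sd_between: float = 5.0
    per_call_depth: bool = True  # False: constant depth per sample (fast Monte Carlo)
    missing_rate: float = 0.02
    n_related_pairs: int = 0
    n_qc_outliers: int = 0
    n_common_snps: int = 1372  # matches the study's LD-pruned common-SNP count
    divergence: float = 0.1  # Balding-Nichols Fst between super-populations
    pop_freq_jitter_sd: float = 0.3  # lognormal sd of per-population rare-freq offsets
    seed: int = 0

    def __post_init__(self):
        total = sum(self.population_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population proportions sum to {total}, not 1")
        if min(self.n_cases, self.n_controls, self.n_genes, self.n_related_pairs,
               self.n_qc_outliers, self.n_common_snps) < 0:
            raise ValueError("counts must be non-negative")
        if self.target_ptv_or <= 0 or self.baseline_shift_or <= 0:
            raise ValueError("odds ratios must be positive")
        lo, hi = self.rare_allele_freq_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("rare_allele_freq_range must satisfy 0 < lo <= hi < 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class _FrequencyModel:
    """Seed-determined tables shared by cohort and reference generation."""

    panel: pd.DataFrame
    variants: pd.DataFrame
    pop_freq: np.ndarray  # population x variant allele frequency (controls)
    enriched_genes: frozenset


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _frequency_model(config: SimulationConfig) -> _FrequencyModel:
    """Panel, variant table and per-population allele frequencies.

    Deterministic in ``config.seed`` alone, so a cohort and a reference
    panel generated from the same config share the common-SNP frequency
    model.
    """
    rng = _rng(config, 0)
    n_pops = len(SUPER_POPULATIONS)
    pops = [p for p in SUPER_POPULATIONS if p in config.population_mix]

    genes = [f"G{i+1:04d}" for i in range(config.n_genes)]
    n_constrained = int(round(config.constrained_fraction * config.n_genes))
    constrained = np.zeros(config.n_genes, dtype=bool)
    constrained[rng.choice(config.n_genes, size=n_constrained, replace=False)] = True
    pli = np.where(constrained, rng.uniform(0.91, 1.0, config.n_genes),
                   rng.uniform(0.0, 0.9, config.n_genes))
    panel = pd.DataFrame({"pli": pli, "constrained": constrained},
                         index=pd.Index(genes, name="gene"))

    rows = []
    freqs = []
    lo, hi = config.rare_allele_freq_range
    v = 0
    bases = "ACGT"
    for gi, gene in enumerate(genes):
        pos = 100_000 * (gi + 1)
        for cls, count in config.variants_per_gene_by_class.items():
            for j in range(count):
                v += 1
                pos += 50
                base = rng.uniform(lo, hi)
                jitter = rng.lognormal(0.0, config.pop_freq_jitter_sd, len(pops))
                f = np.clip(base * jitter, lo / 10, 0.01)
                ref, alt = (str(x) for x in rng.choice(list(bases), 2, replace=False))
                cons = str(rng.choice(_CONSEQUENCE_FOR_CLASS[cls]))
                if cons == "frameshift_variant":
                    alt = ref + str(rng.choice(list(bases)))
                mpc = {"missense_tier1": rng.uniform(3.01, 5.0),
                       "missense_tier2": rng.uniform(2.0, 3.0),
                       "missense_nondamaging": rng.uniform(0.0, 1.99)}.get(cls, np.nan)
                rows.append({"variant_id": f"V{v:06d}", "chrom": "1", "pos": pos,
                             "ref": ref, "alt": alt, "gene": gene, "consequence": cons,
                             "mpc": mpc, "class_true": cls})
                freqs.append(f)
    # Common SNPs for population structure. Population allele-frequency
    # deviations live on rank-3 ancestry coordinates so that, as in real
    # continental data, the top three principal components capture the full
    # between-population structure; the deviation variance per SNP matches
    # the Balding-Nichols scale Fst * p * (1 - p).
    anc = rng.uniform(0.1, 0.9, config.n_common_snps)
    Fst = config.divergence
    coords = np.array([_POP_COORDS[p] for p in pops])  # pops x 3, unit norm
    delta = rng.normal(0.0, 1.0, (config.n_common_snps, 3))
    scale = np.sqrt(Fst * anc * (1 - anc))
    common = np.clip(anc[:, None] + scale[:, None] * (delta @ coords.T), 0.01, 0.99)
    for s in range(config.n_common_snps):
        v += 1
        gene = genes[s % len(genes)]
        ref, alt = (str(x) for x in rng.choice(list(bases), 2, replace=False))
        rows.append({"variant_id": f"V{v:06d}", "chrom": "1",
                     "pos": 100_000 * (genes.index(gene) + 1) + 90_000 + s,
                     "ref": ref, "alt": alt, "gene": gene,
                     "consequence": "intron_variant", "mpc": np.nan,
                     "class_true": "common_snp"})
        freqs.append(common[s])
    variants = pd.DataFrame(rows).set_index("variant_id")
    pop_freq = np.array(freqs).T  # pops x variants
    return _FrequencyModel(panel=panel, variants=variants, pop_freq=pop_freq,
                           enriched_genes=frozenset(panel.index[constrained]))


def _tilt(freq: np.ndarray, odds_ratio: float) -> np.ndarray:
    """Allele frequency after multiplying the allele odds by ``odds_ratio``."""
    odds = freq / (1 - freq) * odds_ratio
    return odds / (1 + odds)


def _case_freqs(model: _FrequencyModel, config: SimulationConfig) -> np.ndarray:
    """Per-population allele frequencies in cases after exponential tilting.

    The prospective disease model is logistic with coefficient
    log(target_ptv_or) on the enriched-gene PTV count and coefficient
    log(baseline_shift_or) on every other rare coding count (non-enriched
    PTVs, missense, synonymous). Keeping the enriched-gene PTV term separate
    from the baseline term makes the downstream regression exactly correctly
    specified: its burden coefficient is log(target_ptv_or) and, with
    target_ptv_or = 1, the PTV test stays null no matter the baseline shift
    — the situation the baseline covariate exists to protect against.
    """
    f = model.pop_freq.copy()
    cls = model.variants["class_true"].to_numpy()
    in_enriched = model.variants["gene"].isin(model.enriched_genes).to_numpy()
    ptv_target = (cls == "PTV") & in_enriched
    baseline = np.isin(cls, _CODING_CLASSES) & ~ptv_target
    if config.baseline_shift_or != 1.0:
        f[:, baseline] = _tilt(f[:, baseline], config.baseline_shift_or)
    if config.target_ptv_or != 1.0:
        f[:, ptv_target] = _tilt(f[:, ptv_target], config.target_ptv_or)
    return f


def _draw_depths(rng, depth_means: np.ndarray, m: int, per_call: bool) -> np.ndarray:
    if per_call:
        return rng.poisson(depth_means[:, None], size=(len(depth_means), m)).astype(np.int32)
    return np.repeat(depth_means.round().astype(np.int32)[:, None], m, axis=1)


def _draw_genotypes(rng, pop_idx: np.ndarray, phenotype: np.ndarray,
                    f_control: np.ndarray, f_case: np.ndarray) -> np.ndarray:
    n, m = len(pop_idx), f_control.shape[1]
    out = np.empty((n, m), dtype=np.int8)
    for p in range(f_control.shape[0]):
        for ph, f in ((0, f_control), (1, f_case)):
            rows = np.flatnonzero((pop_idx == p) & (phenotype == ph))
            if rows.size:
                out[rows] = rng.binomial(2, f[p], size=(rows.size, m)).astype(np.int8)
    return out


def _qc_metrics(rng, n: int, depth_means: np.ndarray,
                missing_frac: np.ndarray) -> pd.DataFrame:
    """Nine per-sample QC metrics drawn comfortably inside the thresholds."""
    return pd.DataFrame({
        "mapped_reads": rng.normal(2e6, 2e5, n).clip(min=8e5),
        "mean_depth": depth_means,
        "on_target": rng.normal(92, 2.5, n).clip(max=100, min=82),
        "uniformity": rng.normal(85, 4, n).clip(max=100, min=67),
        "missing_call_rate": missing_frac,
        "inbreeding_f": rng.normal(0.02, 0.08, n).clip(min=-0.5, max=0.55),
        "het_hom_ratio": rng.normal(1.8, 0.25, n).clip(min=0.7),
        "total_snps": rng.normal(1500, 150, n).clip(min=600).round(),
        "total_indels": rng.normal(60, 12, n).clip(min=15).round(),
    })


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a case-control cohort under ``config``.

    Deterministic given the seed. Applies, in order: genotype draws with the
    case tilting described in the module docstring, per-call depths,
    random no-calls at ``missing_rate``, related-pair copying and QC-metric
    generation (with ``plant_qc_outliers`` applied when requested).
    """
    model = _frequency_model(config)
    rng = _rng(config, 1)
    pops = [p for p in SUPER_POPULATIONS if p in config.population_mix]
    probs = np.array([config.population_mix[p] for p in pops])
    n = config.n_cases + config.n_controls
    phenotype = np.concatenate([np.ones(config.n_cases, dtype=int),
                                np.zeros(config.n_controls, dtype=int)])
    pop_idx = rng.choice(len(pops), size=n, p=probs)
    f_case = _case_freqs(model, config)
    dosages = _draw_genotypes(rng, pop_idx, phenotype, model.pop_freq, f_case)

    # read depths: per-sample mean (clipped well above the QC threshold for
    # non-planted samples), Poisson per call
    depth_means = rng.normal(config.depth_mean, config.depth_sd_between, n).clip(min=44)
    depths = _draw_depths(rng, depth_means, dosages.shape[1], config.per_call_depth)

    # related pairs: overwrite the second member's genotypes from the first,
    # resampling each site from the population model at rate (1 - 2*kinship)
    related_pairs = []
    if config.n_related_pairs:
        if 2 * config.n_related_pairs > n:
            raise ValueError("too many related pairs requested")
        chosen = rng.choice(n, size=2 * config.n_related_pairs, replace=False)
        for k in range(config.n_related_pairs):
            a, b = chosen[2 * k], chosen[2 * k + 1]
            kin_class, kin = ("duplicate", 0.5) if k % 2 == 0 else ("first_degree", 0.25)
            resample = rng.random(dosages.shape[1]) > 2 * kin
            row = dosages[a].copy()
            fresh = rng.binomial(2, model.pop_freq[pop_idx[b]]).astype(np.int8)
            row[resample] = fresh[resample]
            dosages[b] = row
            related_pairs.append((f"S{a+1:06d}", f"S{b+1:06d}", kin_class))

    # missingness: random no-calls
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)
    missing_frac = (dosages == MISSING).mean(axis=1)

    sample_ids = pd.Index([f"S{i+1:06d}" for i in range(n)], name="sample_id")
    metrics = _qc_metrics(rng, n, depths.mean(axis=1), missing_frac)
    samples = pd.DataFrame({
        "phenotype": phenotype,
        "population": [pops[i] for i in pop_idx],
        "has_snp_array": rng.random(n) < 0.5,
        "has_sex": rng.random(n) < 0.9,
    }, index=sample_ids)
    samples = pd.concat([samples, metrics.set_index(sample_ids)], axis=1)

    truth = TruthRecord(
        true_or=config.target_ptv_or,
        enriched_genes=model.enriched_genes,
        planted_outlier_ids=frozenset(),
        related_pairs=related_pairs,
    )
    cohort = CohortBundle(dosages=dosages, depths=depths, samples=samples,
                          variants=model.variants.copy(), panel=model.panel.copy(),
                          truth=truth)
    if config.n_qc_outliers:
        cohort = plant_qc_outliers(cohort, config)
    return cohort


def simulate_reference_panel(config: SimulationConfig, n_per_pop: int = 100) -> CohortBundle:
    """Labelled reference samples sharing the cohort's common-SNP frequency model.

    Draws ``n_per_pop`` samples per super-population at the (control)
    population frequencies; the phenotype column is present but unused (0).
    """
    model = _frequency_model(config)
    rng = _rng(config, 2)
    pops = [p for p in SUPER_POPULATIONS if p in config.population_mix]
    n = n_per_pop * len(pops)
    pop_idx = np.repeat(np.arange(len(pops)), n_per_pop)
    phenotype = np.zeros(n, dtype=int)
    dosages = _draw_genotypes(rng, pop_idx, phenotype, model.pop_freq, model.pop_freq)
    depth_means = rng.normal(config.depth_mean, config.depth_sd_between, n).clip(min=44)
    depths = _draw_depths(rng, depth_means, dosages.shape[1], config.per_call_depth)
    sample_ids = pd.Index([f"R{i+1:06d}" for i in range(n)], name="sample_id")
    samples = pd.DataFrame({"phenotype": phenotype,
                            "population": [pops[i] for i in pop_idx]},
                           index=sample_ids)
    return CohortBundle(dosages=dosages, depths=depths, samples=samples,
                        variants=model.variants.copy(), panel=model.panel.copy(),
                        truth=None)


#: per planted outlier, one QC metric pushed past its threshold; the drawn
#: value sits strictly on the violating side
_OUTLIER_DRAWS = {
    "mapped_reads": (1e5, 3.9e5),
    "mean_depth": (15.0, 39.0),
    "on_target": (40.0, 79.0),
    "uniformity": (30.0, 64.0),
    "missing_call_rate": (0.35, 0.8),
    "inbreeding_f": (0.65, 0.95),
    "het_hom_ratio": (0.1, 0.55),
    "total_snps": (50, 390),
    "total_indels": (0, 9),
}


def plant_qc_outliers(cohort: CohortBundle, config: SimulationConfig) -> CohortBundle:
    """Push ``config.n_qc_outliers`` samples past at least one QC threshold.

    Each planted sample gets one randomly chosen metric redrawn beyond its
    threshold; the truth record lists the planted ids.
    """
    k = config.n_qc_outliers
    n = len(cohort.samples)
    if k > n:
        raise ValueError("more QC outliers requested than samples")
    if k == 0:
        return cohort
    rng = _rng(config, 3)
    idx = rng.choice(n, size=k, replace=False)
    samples = cohort.samples.copy()
    metric_names = list(_OUTLIER_DRAWS)
    for i in idx:
        m = metric_names[rng.integers(len(metric_names))]
        lo, hi = _OUTLIER_DRAWS[m]
        val = rng.uniform(lo, hi)
        if m in ("total_snps", "total_indels"):
            val = float(int(val))
        samples.iloc[i, samples.columns.get_loc(m)] = val
    planted = frozenset(cohort.samples.index[idx])
    truth = replace(cohort.truth or TruthRecord(), planted_outlier_ids=planted)
    return replace(cohort, samples=samples, truth=truth)


def simulate_cohort_summaries(n_cohorts: int, shared_signal_genes, seed: int,
                              n_genes: int = 1000, signal_mean_z: float = 3.0,
                              n_cases: int = 20_000, n_controls: int = 20_000,
                              n_trios: int = 0) -> list[CohortSummary]:
    """Gene-level summary-statistic fixtures for meta-analysis.

    Null genes get uniform two-sided p-values with random directions; genes
    in ``shared_signal_genes`` get positive-direction z-scores centred at
    ``signal_mean_z`` in every cohort.
    """
    from scipy import stats

    if n_cohorts < 1:
        raise ValueError("need at least one cohort")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    genes = [f"G{i+1:04d}" for i in range(n_genes)]
    signal = set(shared_signal_genes)
    unknown = signal - set(genes)
    if unknown:
        genes = genes + sorted(unknown)
    out = []
    for c in range(n_cohorts):
        z = rng.normal(0.0, 1.0, len(genes))
        sig_mask = np.array([g in signal for g in genes])
        z[sig_mask] = rng.normal(signal_mean_z, 1.0, int(sig_mask.sum()))
        p = 2 * stats.norm.sf(np.abs(z))
        direction = np.where(z >= 0, 1, -1)
        gene_stats = pd.DataFrame({"p_value": p, "direction": direction},
                                  index=pd.Index(genes, name="gene"))
        out.append(CohortSummary(name=f"cohort_{c+1}", n_cases=n_cases,
                                 n_controls=n_controls, n_trios=n_trios,
                                 gene_stats=gene_stats))
    return out
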