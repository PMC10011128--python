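"""End-to-end orchestration: simulate -> QC -> ancestry -> annotate -> enrich
-> gene tests -> meta, with a reconciled run report.

All randomness flows from the single seed in the configuration, so a rerun
with the same config produces byte-identical machine-readable outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import ancestry as anc
from . import burden as bd
from . import genes as ga
from . import io as bio
from . import meta as ma
from . import qc
from .annotation import RareVariantConfig, classify_variants
from .simulate import SimulationConfig, simulate_cohort, simulate_reference_panel

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "qc", "ancestry", "annotate", "enrich", "genetest", "meta")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES[:-1]))  # meta opt-in
    cohort_dir: str | None = None  # load instead of simulating when "simulate" absent
    out_dir: str = "burdenmeta_out"
    simulation: dict = field(default_factory=dict)
    rare_mode: str = "mac"
    mac_max: int = 5
    maf_max: float = 0.001
    analysis_mode: str = "combined"  # or "stratified"
    qc_thresholds: dict = field(default_factory=dict)
    kinship_flag: float = qc.KINSHIP_FLAG
    knn_k: int = 5
    knn_components: int = 3
    outlier_n_sd: float = 6.0
    outlier_max_rounds: int = 5
    n_reference_per_pop: int = 100
    alpha: float = 0.05
    n_classes_tested: int = 5
    gene_test_n_tests: int = 161
    cohort_summaries: list = field(default_factory=list)  # TSV paths for meta stage

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.analysis_mode not in ("combined", "stratified"):
            raise ValueError("analysis_mode must be 'combined' or 'stratified'")
        if self.analysis_mode == "stratified" and "ancestry" not in self.stages:
            raise ValueError("stratified analysis requires the ancestry stage")
        if "simulate" not in self.stages and self.cohort_dir is None:
            raise ValueError("either enable the simulate stage or give cohort_dir")

    def rare_config(self) -> RareVariantConfig:
        return RareVariantConfig(mode=self.rare_mode, mac_max=self.mac_max,
                                 maf_max=self.maf_max)


@dataclass
class RunReport:
    """Per-stage record counts, exclusion tallies and wall time."""

    config: dict
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> output TSV path
    version: str = ""

    def reconcile(self) -> None:
        """Assert in = retained + excluded wherever both were recorded."""
        for stage, rec in self.stage_counts.items():
            if {"in", "retained", "excluded"} <= set(rec):
                if rec["in"] != rec["retained"] + rec["excluded"]:
                    raise AssertionError(f"record counts do not reconcile at {stage}: {rec}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in fixed order; see module docstring."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), version=__version__)

    def timed(stage):
        t0 = time.perf_counter()
        return lambda: report.stage_seconds.__setitem__(stage, time.perf_counter() - t0)

    # --- obtain cohort -----------------------------------------------------
    done = timed("simulate")
    if "simulate" in config.stages:
        sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
        cohort = simulate_cohort(sim)
        bio.write_cohort(cohort, out / "cohort")
    else:
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        cohort = bio.read_cohort(config.cohort_dir)
    done()
    report.stage_counts["simulate"] = {"samples": len(cohort.samples),
                                       "variants": len(cohort.variants)}

    # --- QC ----------------------------------------------------------------
    if "qc" in config.stages:
        done = timed("qc")
        n_in = len(cohort.samples)
        resolved = qc.resolve_no_calls(cohort.dosages, cohort.depths)
        cohort = type(cohort)(dosages=resolved, depths=cohort.depths,
                              samples=cohort.samples, variants=cohort.variants,
                              panel=cohort.panel, truth=cohort.truth)
        thresholds = qc.SampleQCThresholds(**config.qc_thresholds)
        retained, excluded = qc.apply_sample_qc(cohort.samples[list(qc.METRIC_COLUMNS)],
                                                thresholds)
        bio.write_tsv(excluded, out / "excluded_samples.tsv")
        report.tables["excluded_samples"] = str(out / "excluded_samples.tsv")
        cohort = cohort.subset_samples(retained)
        keep_v, drop_v = qc.apply_site_filter(cohort.dosages, cohort.variant_ids)
        cohort = cohort.subset_variants(keep_v)
        # relatedness pruning from generator truth (or an external kinship table)
        if cohort.truth is not None and cohort.truth.related_pairs:
            pairs = pd.DataFrame(
                [(a, b) for a, b, _ in cohort.truth.related_pairs
                 if a in cohort.sample_ids and b in cohort.sample_ids],
                columns=["id_a", "id_b"])
            if len(pairs):
                attrs = _relative_attributes(cohort, pairs)
                kept = qc.prune_relatives(pairs, attrs)
                # prune_relatives only ever drops members of flagged pairs
                cohort = cohort.subset_samples(
                    cohort.sample_ids[cohort.sample_ids.isin(kept)
                                      | ~cohort.sample_ids.isin(attrs.index)])
        done()
        report.stage_counts["qc"] = {"in": n_in, "retained": len(cohort.samples),
                                     "excluded": n_in - len(cohort.samples),
                                     "variants_dropped": len(drop_v)}

    # --- ancestry ----------------------------------------------------------
    pcs = None
    assigned = None
    if "ancestry" in config.stages:
        done = timed("ancestry")
        ref = simulate_reference_panel(SimulationConfig(**{"seed": config.seed,
                                                           **config.simulation}),
                                       n_per_pop=config.n_reference_per_pop)
        snp_ids = anc.select_pca_snps(cohort.variants, cohort.dosages)
        shared = [s for s in snp_ids if s in ref.variant_ids]
        ref_sub = ref.subset_variants(shared)
        coh_sub = cohort.subset_variants(shared)
        model, joint, assignments = anc.fit_joint_ancestry(
            ref_sub.dosages, ref_sub.sample_ids, ref_sub.samples["population"],
            coh_sub.dosages, coh_sub.sample_ids,
            k_neighbors=config.knn_k, n_components_for_knn=config.knn_components)
        assigned = assignments["assigned_pop"]
        pcs = joint.scores.loc[cohort.sample_ids]
        bio.write_tsv(pcs, out / "pca_scores.tsv")
        bio.write_tsv(assignments, out / "ancestry_assignments.tsv")
        report.tables["ancestry_assignments"] = str(out / "ancestry_assignments.tsv")
        done()
        report.stage_counts["ancestry"] = {"snps_used": len(shared),
                                           "assigned": len(assigned)}

    # --- annotation --------------------------------------------------------
    if "annotate" in config.stages:
        done = timed("annotate")
        variants = classify_variants(cohort.variants)
        cohort = type(cohort)(dosages=cohort.dosages, depths=cohort.depths,
                              samples=cohort.samples, variants=variants,
                              panel=cohort.panel, truth=cohort.truth)
        bio.write_tsv(variants[["gene", "consequence", "mpc", "variant_class"]],
                      out / "variant_classes.tsv")
        done()
        report.stage_counts["annotate"] = dict(
            variants["variant_class"].value_counts())

    # --- enrichment --------------------------------------------------------
    if "enrich" in config.stages:
        done = timed("enrich")
        if pcs is None:
            raise ValueError("enrich stage requires the ancestry stage")
        stratified = config.analysis_mode == "stratified"
        classes = (("ptv_mpc3", "missense_tier2", "synonymous") if stratified
                   else ("PTV", "missense_tier1", "missense_tier2",
                         "missense_nondamaging", "synonymous"))
        frames = [bd.global_enrichment_test(
            cohort, pcs, variant_class=cls, stratified=stratified,
            ancestry_labels=assigned if stratified else None,
            rare_config=None if stratified else config.rare_config(),
            alpha=config.alpha, n_classes_tested=config.n_classes_tested)
            for cls in classes]
        enrich = pd.concat(frames, ignore_index=True)
        bio.write_tsv(enrich, out / "enrichment.tsv", index=False)
        report.tables["enrichment"] = str(out / "enrichment.tsv")
        done()
        report.stage_counts["enrich"] = {"rows": len(enrich)}

    # --- per-gene tests ----------------------------------------------------
    if "genetest" in config.stages:
        done = timed("genetest")
        counts = gene_count_table(cohort, config.rare_config())
        results = ga.gene_burden_table(counts)
        thr = ma.bonferroni_threshold([config.gene_test_n_tests], config.alpha)
        results["significant"] = results["p_value"] < thr
        bio.write_tsv(results, out / "gene_tests.tsv")
        report.tables["gene_tests"] = str(out / "gene_tests.tsv")
        done()
        report.stage_counts["genetest"] = {"genes": len(results),
                                           "significant": int(results["significant"].sum())}

    # --- meta --------------------------------------------------------------
    if "meta" in config.stages and config.cohort_summaries:
        done = timed("meta")
        cohorts = [_load_cohort_summary(p) for p in config.cohort_summaries]
        combined = ma.meta_analyze(cohorts)
        bio.write_tsv(combined, out / "meta.tsv")
        report.tables["meta"] = str(out / "meta.tsv")
        done()
        report.stage_counts["meta"] = {"genes": len(combined)}

    report.reconcile()
    return report


def gene_count_table(cohort: CohortBundle, rare_config: RareVariantConfig,
                     ) -> pd.DataFrame:
    """Per-gene PTV-allele counts by phenotype (rare variants only)."""
    from .annotation import rare_mask
    import numpy as np
    from .cohort import MISSING

    counts = cohort.allele_counts()
    ok = counts["total_alleles"].to_numpy() > 0
    rare = np.zeros(len(counts), dtype=bool)
    rare[ok] = rare_mask(counts["alt_count"].to_numpy()[ok],
                         counts["total_alleles"].to_numpy()[ok], rare_config)
    is_ptv = (cohort.variants["variant_class"] == "PTV").to_numpy() & rare
    case = (cohort.samples["phenotype"] == 1).to_numpy()
    dos = np.where(cohort.dosages == MISSING, 0, cohort.dosages)
    called = cohort.dosages != MISSING
    rows = []
    for gene in cohort.panel.index:
        vmask = (cohort.variants["gene"] == gene).to_numpy() & is_ptv
        allm = (cohort.variants["gene"] == gene).to_numpy()
        rows.append({
            "gene": gene,
            "ptv_cases": int(dos[np.ix_(case, vmask)].sum()),
            "ptv_controls": int(dos[np.ix_(~case, vmask)].sum()),
            "total_cases": int(2 * case.sum()),
            "total_controls": int(2 * (~case).sum()),
        })
    return pd.DataFrame(rows).set_index("gene")


def _relative_attributes(cohort: CohortBundle, pairs: pd.DataFrame) -> pd.DataFrame:
    """Retention attributes for every sample named in a flagged pair."""
    ids = sorted(set(pairs["id_a"]) | set(pairs["id_b"]))
    n_rel = pd.concat([pairs["id_a"], pairs["id_b"]]).value_counts()
    s = cohort.samples
    return pd.DataFrame({
        "n_relatives": [int(n_rel.get(i, 0)) for i in ids],
        "phenotype": [int(s.loc[i, "phenotype"]) for i in ids],
        "has_snp_array": [bool(s.loc[i, "has_snp_array"]) if "has_snp_array" in s else False
                          for i in ids],
        "has_sex": [bool(s.loc[i, "has_sex"]) if "has_sex" in s else False for i in ids],
        "rare_missingness": [float((cohort.dosages[s.index.get_loc(i)] == -1).mean())
                             for i in ids],
    }, index=pd.Index(ids, name="sample_id"))


def _load_cohort_summary(path) -> ma.CohortSummary:
    """Load a cohort summary TSV: needs attrs row conventions documented in io."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = {"cohort", "n_cases", "n_controls", "n_trios"}
    if not meta_cols <= set(df.columns):
        raise ValueError(f"cohort summary {path} missing columns {meta_cols - set(df.columns)}")
    first = df.iloc[0]
    gene_stats = df.set_index("gene")[["p_value", "direction"]]
    return ma.CohortSummary(name=str(first["cohort"]), n_cases=int(first["n_cases"]),
                            n_controls=int(first["n_controls"]),
                            n_trios=int(first["n_trios"]), gene_stats=gene_stats)
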