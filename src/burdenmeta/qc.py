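"""Genotype-, sample- and site-level quality control plus relatedness pruning.

The stage order used by the pipeline is: no-call resolution (a no-call
becomes homozygous reference when its read depth exceeds ten, otherwise
stays missing), then sample-level exclusion on nine per-sample metrics
(every threshold a strict inequality), then a site-level filter removing
variants with more than 10% missing calls, and finally one-per-pair pruning
of flagged relative pairs under an ordered retention scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING

#: depth above which an unresolved no-call is promoted to homozygous reference
NO_CALL_DEPTH = 10

#: kinship coefficient at/above which a pair is flagged (3rd-degree convention)
KINSHIP_FLAG = 0.0442


@dataclass(frozen=True)
class SampleQCThresholds:
    """The nine per-sample exclusion thresholds; all comparisons are strict."""

    mapped_reads_min: float = 400_000
    mean_depth_min: float = 40
    on_target_min: float = 80
    uniformity_min: float = 65
    missing_call_rate_max: float = 0.3
    inbreeding_f_max: float = 0.6
    het_hom_ratio_min: float = 0.6
    total_snps_min: float = 400
    total_indels_min: float = 10


#: metric column -> (threshold attribute, direction); "low" excludes below,
#: "high" excludes above
METRIC_RULES = {
    "mapped_reads": ("mapped_reads_min", "low"),
    "mean_depth": ("mean_depth_min", "low"),
    "on_target": ("on_target_min", "low"),
    "uniformity": ("uniformity_min", "low"),
    "missing_call_rate": ("missing_call_rate_max", "high"),
    "inbreeding_f": ("inbreeding_f_max", "high"),
    "het_hom_ratio": ("het_hom_ratio_min", "low"),
    "total_snps": ("total_snps_min", "low"),
    "total_indels": ("total_indels_min", "low"),
}

METRIC_COLUMNS = tuple(METRIC_RULES)


def resolve_no_calls(dosages: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Promote well-covered no-calls to homozygous reference.

    A missing dosage becomes 0 iff its depth is strictly greater than
    :data:`NO_CALL_DEPTH`; called genotypes are untouched.
    """
    if (np.asarray(depths) < 0).any():
        raise ValueError("negative read depth")
    dosages = np.asarray(dosages)
    out = dosages.copy()
    out[(dosages == MISSING) & (depths > NO_CALL_DEPTH)] = 0
    return out


def apply_sample_qc(metrics: pd.DataFrame,
                    thresholds: SampleQCThresholds = SampleQCThresholds(),
                    ) -> tuple[pd.Index, pd.DataFrame]:
    """Exclude samples violating any of the nine metric thresholds.

    Returns (retained sample ids, exclusion table). The exclusion table is
    indexed by sample id with a ``reasons`` column listing every violated
    criterion. A sample sitting exactly on a boundary passes (strict
    inequalities).
    """
    for col in METRIC_COLUMNS:
        if col not in metrics.columns:
            raise ValueError(f"sample QC metric column missing: {col}")
        bad = metrics.index[metrics[col].isna()]
        if len(bad):
            raise ValueError(f"sample {bad[0]} missing metric {col}")
    reasons: dict[object, list[str]] = {}
    for col, (attr, direction) in METRIC_RULES.items():
        cut = getattr(thresholds, attr)
        viol = metrics[col] < cut if direction == "low" else metrics[col] > cut
        for sid in metrics.index[viol]:
            reasons.setdefault(sid, []).append(col)
    excluded = pd.DataFrame(
        {"reasons": [";".join(reasons[s]) for s in metrics.index if s in reasons]},
        index=pd.Index([s for s in metrics.index if s in reasons], name=metrics.index.name),
    )
    retained = metrics.index[~metrics.index.isin(excluded.index)]
    return retained, excluded


def apply_site_filter(dosages: np.ndarray, variant_ids: pd.Index,
                      max_missing: float = 0.10) -> tuple[pd.Index, pd.Index]:
    """Drop variants whose missing-call fraction strictly exceeds ``max_missing``."""
    dosages = np.asarray(dosages)
    if dosages.shape[0] == 0:
        raise ValueError("no samples")
    miss = (dosages == MISSING).mean(axis=0)
    keep = miss <= max_missing
    return variant_ids[keep], variant_ids[~keep]


def compare_exclusions_by_phenotype(n_excluded_cases: int, n_total_cases: int,
                                    n_excluded_controls: int, n_total_controls: int,
                                    continuity_correction: bool = True,
                                    ) -> tuple[float, float]:
    """Chi-square test that QC exclusion rates differ by phenotype.

    Pearson chi-square on the 2x2 excluded/retained x case/control table,
    with Yates continuity correction by default. Returns (statistic, p).
    """
    if n_total_cases <= 0 or n_total_controls <= 0:
        raise ValueError("group totals must be positive")
    if n_excluded_cases > n_total_cases or n_excluded_controls > n_total_controls:
        raise ValueError("excluded count exceeds group total")
    table = np.array(
        [[n_excluded_cases, n_total_cases - n_excluded_cases],
         [n_excluded_controls, n_total_controls - n_excluded_controls]]
    )
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def prune_relatives(pairs: pd.DataFrame, attributes: pd.DataFrame) -> pd.Index:
    """Resolve flagged relative pairs, keeping one member of each.

    ``pairs`` has columns ``id_a, id_b`` (optionally ``kinship``); every row
    is a flagged pair. ``attributes`` is indexed by sample id with columns
    ``n_relatives, phenotype, has_snp_array, has_sex, rare_missingness``.

    Per pair the member to KEEP is chosen by ordered rules: fewer relatives
    in the whole cohort; case over control; has genome-wide SNP data; has
    self-reported sex; lower missingness among rare variants; and finally
    lexicographically smaller id. Pairs are resolved in sorted order until
    no flagged pair survives among the retained samples.
    """
    ids = set(attributes.index)
    for col in ("id_a", "id_b"):
        unknown = set(pairs[col]) - ids
        if unknown:
            raise ValueError(f"kinship pair references unknown sample(s): {sorted(unknown)[:5]}")
    if (pairs["id_a"] == pairs["id_b"]).any():
        raise ValueError("self-pair in kinship table")

    def keep_of(a: str, b: str) -> str:
        ra, rb = attributes.loc[a], attributes.loc[b]
        for key, better in (
            ("n_relatives", min),
            ("phenotype", max),
            ("has_snp_array", max),
            ("has_sex", max),
            ("rare_missingness", min),
        ):
            va, vb = ra[key], rb[key]
            if va != vb:
                return a if better(va, vb) == va else b
        return min(a, b)

    retained = set(attributes.index)
    edges = sorted((min(r.id_a, r.id_b), max(r.id_a, r.id_b))
                   for r in pairs.itertuples(index=False))
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            if a in retained and b in retained:
                loser = b if keep_of(a, b) == a else a
                retained.discard(loser)
                changed = True
    return attributes.index[attributes.index.isin(retained)]


def flag_pairs(kinship: pd.DataFrame, threshold: float = KINSHIP_FLAG) -> pd.DataFrame:
    """Subset a kinship table (id_a, id_b, kinship) to pairs at/above threshold."""
    return kinship.loc[kinship["kinship"] >= threshold, :].copy()
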