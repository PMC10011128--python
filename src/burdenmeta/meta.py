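"""Cross-cohort evidence combination.

Gene-level two-sided p-values from different cohorts are combined with
signed Stouffer's method: each p is converted to a direction-signed normal
quantile z_i = d_i * Phi^{-1}(1 - p_i/2) and the combined statistic is

    Z = sum(w_i * z_i) / sqrt(sum(w_i**2))

with study weights w_i the effective sample size

    w = 4 / (1/n_cases + 1/n_controls) + n_trios

which puts case-control data and trio data on an equal footing. Enrichment
odds ratios are combined on the log scale by fixed-effect inverse-variance
weighting, and multiplicity thresholds are plain Bonferroni over the summed
test counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# smallest p whose normal quantile is still comfortably finite
_P_FLOOR = 1e-300


@dataclass
class CohortSummary:
    """One cohort's gene-level evidence: sizes plus per-gene p and direction."""

    name: str
    n_cases: int
    n_controls: int
    n_trios: int = 0
    #: DataFrame indexed by gene: columns p_value, direction (+1/-1),
    #: optionally log_or and se for inverse-variance meta-analysis
    gene_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def weight(self) -> float:
        return effective_weight(self.n_cases, self.n_controls, self.n_trios)


@dataclass(frozen=True)
class MetaResult:
    gene: str
    z_scores: tuple
    weights: tuple
    z_combined: float
    p_value: float
    direction: int
    cohorts: tuple


def effective_weight(n_cases: int, n_controls: int, n_trios: int = 0) -> float:
    """Effective-sample-size study weight: 4/(1/cases + 1/controls) + trios."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if n_trios < 0:
        raise ValueError("trio count must be non-negative")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls) + n_trios


def _z_from_p(p: float, direction: float) -> float:
    """Signed z from a two-sided p (p=1 maps to z=0; p=0 clamped with warning)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p == 0:
        logger.warning("p-value of exactly 0 clamped to smallest representable")
        p = _P_FLOOR
    z = stats.norm.isf(p / 2.0)
    return float(np.sign(direction) * z) if z != 0 else 0.0

def signed_stouffer(entries, gene: str = "", sqrt_weights: bool = False) -> MetaResult:
    """Combine (p, direction, weight) triples by weighted signed Stouffer.

    ``sqrt_weights=True`` replaces each weight by its square root, the
    conventional sample-size weighting; the default applies the effective-n
    weight literally.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("need at least one cohort entry")
    ps, dirs, ws = zip(*[(float(p), float(d), float(w)) for p, d, w in entries])
    if any(w <= 0 for w in ws):
        raise ValueError("weights must be positive")
    if sqrt_weights:
        ws = tuple(np.sqrt(w) for w in ws)
    zs = tuple(_z_from_p(p, d) for p, d in zip(ps, dirs))
    z = float(np.dot(ws, zs) / np.sqrt(np.dot(ws, ws)))
    if len(entries) == 1:
        # single-cohort meta is the identity: echo the input p to the bit
        p_comb = ps[0]
    else:
        p_comb = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene=gene,
        z_scores=zs,
        weights=ws,
        z_combined=z,
        p_value=min(p_comb, 1.0),
        direction=int(np.sign(z)) if z != 0 else 0,
        cohorts=tuple(range(len(entries))),
    )


def ivw_meta(entries) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance meta of (log OR, SE) pairs.

    Returns (combined log OR, combined SE, two-sided Wald p).
    """
    entries = list(entries)
    if not entries:
        raise ValueError("need at least one entry")
    betas, ses = map(np.asarray, zip(*entries))
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def bonferroni_threshold(n_tests_terms, alpha: float = 0.05) -> float:
    """alpha divided by the summed test counts (e.g. panel + exome tests)."""
    terms = [int(t) for t in n_tests_terms]
    if not terms or any(t < 1 for t in terms):
        raise ValueError("test counts must be positive integers")
    return alpha / sum(terms)


def meta_analyze(cohorts: list[CohortSummary], sqrt_weights: bool = False) -> pd.DataFrame:
    """Signed-Stouffer meta over every gene present in at least one cohort.

    A gene absent from a cohort is combined over the cohorts that do carry
    it (the panel-versus-exome asymmetry), with the skip logged. Returns a
    DataFrame indexed by gene with combined z, p, direction and the list of
    contributing cohorts.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    all_genes = sorted(set().union(*[set(c.gene_stats.index) for c in cohorts]))
    rows = []
    for gene in all_genes:
        entries, used = [], []
        for c in cohorts:
            if gene in c.gene_stats.index:
                row = c.gene_stats.loc[gene]
                entries.append((row["p_value"], row["direction"], c.weight))
                used.append(c.name)
            else:
                logger.debug("gene %s absent from cohort %s; skipped there", gene, c.name)
        res = signed_stouffer(entries, gene=gene, sqrt_weights=sqrt_weights)
        rows.append({"gene": gene, "z": res.z_combined, "p_value": res.p_value,
                     "direction": res.direction, "n_cohorts": len(used),
                     "cohorts": ",".join(used)})
    return pd.DataFrame(rows).set_index("gene")


def cross_disorder_meta(cohorts: list[CohortSummary], alpha: float = 0.05,
                        n_tests_terms=(23321, 161), sqrt_weights: bool = False) -> pd.DataFrame:
    """Meta-analysis across disorders with the exome-wide significance flag.

    Identical machinery to :func:`meta_analyze`; adds a ``significant``
    column at the Bonferroni threshold over ``n_tests_terms``.
    """
    out = meta_analyze(cohorts, sqrt_weights=sqrt_weights)
    thr = bonferroni_threshold(n_tests_terms, alpha)
    out["significant"] = out["p_value"] < thr
    out.attrs["threshold"] = thr
    return out
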