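"""Per-gene exact burden tests on allele-count contingency tables.

Each gene contributes a 2x2 table: PTV alleles vs non-PTV alleles, in cases
vs controls. Association is tested by Fisher's exact test, two-sided under
the minimum-likelihood rule (the convention of the common statistical
implementations), and effect size is the sample (cross-product) odds ratio,
which may legitimately be 0 or +inf when one arm carries no PTV alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: relative slack when comparing point probabilities in the two-sided rule
_REL_TOL = 1e-7


@dataclass(frozen=True)
class GeneTestResult:
    gene: str
    odds_ratio: float
    p_value: float
    ptv_cases: int
    ptv_controls: int
    total_cases: int
    total_controls: int
    method: str = "fisher_exact_two_sided"


def gene_contingency(ptv_cases: int, ptv_controls: int,
                     total_cases: int, total_controls: int) -> np.ndarray:
    """2x2 table [[PTV, non-PTV] x [cases, controls]] from gene-level counts."""
    if ptv_cases > total_cases or ptv_controls > total_controls:
        raise ValueError("PTV allele count exceeds total allele count")
    if min(ptv_cases, ptv_controls, total_cases, total_controls) < 0:
        raise ValueError("negative allele count")
    return np.array(
        [[ptv_cases, total_cases - ptv_cases],
         [ptv_controls, total_controls - ptv_controls]],
        dtype=np.int64,
    )


def sample_odds_ratio(table: np.ndarray) -> float:
    """Cross-product odds ratio (a*d)/(b*c) with the usual boundary conventions.

    Returns ``inf`` when controls carry no events but cases do, ``0.0`` for
    the reverse, and ``nan`` when neither arm has events.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if a == 0 and c == 0:
        return float("nan")
    if c == 0:
        return float("inf")
    if a == 0:
        return 0.0
    if b == 0 or d == 0:
        return float("inf") if d == 0 else 0.0
    return (a * d) / (b * c)


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Exact two-sided Fisher p by the minimum-likelihood method.

    With margins fixed, sums hypergeometric probabilities of every table
    whose point probability does not exceed the observed one (within
    relative tolerance 1e-7). Computed in log space to stay stable for
    large margins.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a = tab[0, 0]
    n = int(tab.sum())
    row1 = int(tab[0].sum())
    k = int(tab[:, 0].sum())  # event-column margin
    if n == 0 or k == 0 or k == n or row1 == 0 or row1 == n:
        return 1.0
    lo = max(0, k - (n - row1))
    hi = min(k, row1)
    support = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(support, n, k, row1)
    log_obs = logpmf[a - lo]
    # include tables at most (1 + 1e-7) times as probable as the observed one
    mask = logpmf <= log_obs + np.log1p(_REL_TOL)
    # log-sum-exp of the selected tail(s)
    m = logpmf[mask].max()
    p = float(np.exp(m) * np.exp(logpmf[mask] - m).sum())
    return min(p, 1.0)


def gene_test(gene: str, ptv_cases: int, ptv_controls: int,
              total_cases: int, total_controls: int) -> GeneTestResult:
    """Fisher exact test and sample OR for one gene's allele counts."""
    table = gene_contingency(ptv_cases, ptv_controls, total_cases, total_controls)
    return GeneTestResult(
        gene=gene,
        odds_ratio=sample_odds_ratio(table),
        p_value=fisher_exact_two_sided(table),
        ptv_cases=ptv_cases,
        ptv_controls=ptv_controls,
        total_cases=total_cases,
        total_controls=total_controls,
    )


def gene_burden_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`gene_test` over a gene-count table.

    ``counts`` is indexed by gene with columns ``ptv_cases, ptv_controls,
    total_cases, total_controls``; returns the same index with ``odds_ratio``
    and ``p_value`` added.
    """
    rows = []
    for gene, row in counts.iterrows():
        res = gene_test(str(gene), int(row["ptv_cases"]), int(row["ptv_controls"]),
                        int(row["total_cases"]), int(row["total_controls"]))
        rows.append({"gene": gene, "odds_ratio": res.odds_ratio, "p_value": res.p_value,
                     **{c: int(row[c]) for c in ("ptv_cases", "ptv_controls",
                                                 "total_cases", "total_controls")}})
    return pd.DataFrame(rows).set_index("gene")


def collective_subset_test(counts: pd.DataFrame, genes,
                           denominator: str = "mean") -> GeneTestResult:
    """Pool PTV allele counts over a gene subset and test the pooled table.

    PTV counts are summed across the subset. Because every gene's total
    allele count refers to (nearly) the same samples, summing totals would
    multiply the denominator by the number of genes; the default therefore
    uses the per-gene mean total (``denominator="mean"``), with ``"sum"``
    available. The pooled OR/p is reported descriptively — the method used
    is echoed on the result.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    sub = counts.loc[genes]
    ptv_ca = int(sub["ptv_cases"].sum())
    ptv_co = int(sub["ptv_controls"].sum())
    if denominator == "mean":
        tot_ca = int(round(sub["total_cases"].mean()))
        tot_co = int(round(sub["total_controls"].mean()))
    elif denominator == "sum":
        tot_ca = int(sub["total_cases"].sum())
        tot_co = int(sub["total_controls"].sum())
    else:
        raise ValueError("denominator must be 'mean' or 'sum'")
    res = gene_test("+".join(map(str, genes)), ptv_ca, ptv_co, tot_ca, tot_co)
    return GeneTestResult(**{**res.__dict__, "method": f"fisher_pooled_{denominator}"})


def direction_consistency_test(signs_a, signs_b) -> tuple[int, int, float]:
    """Exact two-sided binomial test of effect-direction concordance.

    ``signs_a`` and ``signs_b`` are paired direction indicators (+1/-1, 0 or
    NaN meaning undefined); genes with a defined direction in both cohorts
    are compared and the number concordant is tested against 0.5.
    Returns (n_concordant, n_comparable, p).
    """
    a = np.asarray(signs_a, dtype=float)
    b = np.asarray(signs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("direction vectors must align")
    ok = np.isfinite(a) & np.isfinite(b) & (a != 0) & (b != 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no genes with a defined direction in both cohorts")
    conc = int((np.sign(a[ok]) == np.sign(b[ok])).sum())
    p = float(stats.binomtest(conc, n, 0.5, alternative="two-sided").pvalue)
    return conc, n, p
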