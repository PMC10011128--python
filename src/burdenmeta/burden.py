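"""Gene-set rare-variant burden enrichment via Firth-penalized logistic regression.

Per-sample rare-allele counts in a gene set (by variant class) are regressed
on case/control status, adjusting for ancestry principal components and a
baseline rare-variant burden that absorbs residual technical differences
between cases and controls: the rare synonymous count when the burden of
interest is protein-truncating or missense, and the rare nonsynonymous
count when the burden of interest is synonymous.

The regression maximises the Jeffreys-prior-penalised log-likelihood

    l*(b) = l(b) + 0.5 * log |I(b)|

(Firth's correction), which keeps estimates finite under the sparse counts
and occasional complete separation typical of rare-variant data. Newton
iterations use the hat-diagonal-adjusted score; inference is by penalised
likelihood-ratio test (default; Wald optional) and confidence intervals by
profile penalised likelihood (default; Wald optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .annotation import RareVariantConfig, rare_mask
from .cohort import MISSING, CohortBundle

logger = logging.getLogger(__name__)

#: classes countable per sample; composites expand to their members
CLASS_MEMBERS = {
    "PTV": ("PTV",),
    "missense_tier1": ("missense_tier1",),
    "missense_tier2": ("missense_tier2",),
    "missense_nondamaging": ("missense_nondamaging",),
    "synonymous": ("synonymous",),
    "missense": ("missense_tier1", "missense_tier2", "missense_nondamaging"),
    "nonsynonymous": ("PTV", "missense_tier1", "missense_tier2", "missense_nondamaging"),
    "ptv_mpc3": ("PTV", "missense_tier1"),  # PTV + MPC>3 missense, pooled for power
    "coding": ("PTV", "missense_tier1", "missense_tier2", "missense_nondamaging", "synonymous"),
}

#: baseline-burden pairing: synonymous baseline for (non)damaging coding
#: classes, nonsynonymous baseline when the class of interest is synonymous
def baseline_class(variant_class: str) -> str:
    return "nonsynonymous" if variant_class == "synonymous" else "synonymous"


@dataclass
class FirthFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool
    iterations: int
    loglik: float  # penalised log-likelihood at the maximum
    term: int = 1  # design column the OR/p refer to
    columns: tuple = ()


def count_rare_burden(cohort: CohortBundle, gene_set, variant_class: str,
                      rare_config: RareVariantConfig = RareVariantConfig(),
                      ) -> pd.Series:
    """Per-sample summed allele dosage over rare variants of a class in a gene set.

    Rarity is judged from the cohort's own post-QC allele counts; missing
    dosages contribute zero. ``variant_class`` may be a composite
    (``nonsynonymous``, ``ptv_mpc3``, ...) per :data:`CLASS_MEMBERS`.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if "variant_class" not in cohort.variants.columns:
        raise ValueError("variants not yet classified; run annotation first")
    members = CLASS_MEMBERS[variant_class]
    counts = cohort.allele_counts()
    nonmono = counts["total_alleles"].to_numpy() > 0
    rare = np.zeros(len(counts), dtype=bool)
    rare[nonmono] = rare_mask(counts["alt_count"].to_numpy()[nonmono],
                              counts["total_alleles"].to_numpy()[nonmono], rare_config)
    mask = (
        cohort.variants["gene"].isin(gene_set).to_numpy()
        & cohort.variants["variant_class"].isin(members).to_numpy()
        & rare
    )
    dos = np.where(cohort.dosages == MISSING, 0, cohort.dosages)
    return pd.Series(dos[:, mask].sum(axis=1), index=cohort.sample_ids,
                     name=f"burden_{variant_class}")


def _penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    p = expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    W = p * (1 - p)
    _, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
    return ll + 0.5 * logdet


def _firth_newton(X: np.ndarray, y: np.ndarray, free: np.ndarray,
                  beta0: np.ndarray, tol: float = 1e-6, max_iter: int = 100,
                  ) -> tuple[np.ndarray, float, bool, int, np.ndarray]:
    """Maximise the penalised likelihood over the ``free`` coefficients.

    Coefficients outside ``free`` stay at their ``beta0`` values (used for
    profile likelihood). Returns (beta, penalised loglik, converged,
    iterations, covariance of the free block).
    """
    beta = beta0.copy()
    ll = _penalized_loglik(beta, X, y)
    it = 0
    converged = False
    cov_free = np.full((free.sum(), free.sum()), np.nan)
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1 - p)
        XtWX = (X * W[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as err:
            raise ValueError("design matrix is rank deficient") from err
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        score = X.T @ (y - p + h * (0.5 - p))
        score_free = score[free]
        if np.max(np.abs(score_free)) < tol:
            converged = True
            cov_free = np.linalg.inv(XtWX[np.ix_(free, free)])
            break
        cov_free = np.linalg.inv(XtWX[np.ix_(free, free)])
        step = cov_free @ score_free
        # step-halving if the penalised likelihood would decrease
        for _ in range(25):
            cand = beta.copy()
            cand[free] += step
            ll_new = _penalized_loglik(cand, X, y)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = cand
        ll = ll_new
    return beta, ll, converged, it, cov_free


def firth_logistic_fit(y, X, term: int = 1, tol: float = 1e-6, max_iter: int = 100,
                       pvalue_method: str = "lrt", ci_method: str = "profile",
                       alpha: float = 0.05, columns: tuple = ()) -> FirthFit:
    """Fit a Firth-penalised logistic regression.

    Parameters
    ----------
    y : 0/1 outcome vector
    X : design matrix, intercept included as the first column
    term : column whose odds ratio, p-value and confidence interval are
        reported (default 1, the burden column by convention)
    pvalue_method : "lrt" (penalised likelihood-ratio, default) or "wald"
    ci_method : "profile" (profile penalised likelihood, default) or "wald"
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        # name the offending columns for the caller
        _, R = np.linalg.qr(X)
        dep = [i for i in range(k) if abs(R[i, i]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        names = [columns[i] if i < len(columns) else f"col{i}" for i in dep]
        raise ValueError(f"design matrix is rank deficient (collinear: {names})")
    free = np.ones(k, dtype=bool)
    beta, ll, converged, it, cov = _firth_newton(X, y, free, np.zeros(k),
                                                 tol=tol, max_iter=max_iter)
    if not converged:
        logger.warning("Firth fit did not converge in %d iterations", max_iter)
    se = np.sqrt(np.diag(cov))

    if pvalue_method == "lrt":
        ll0 = _profile_loglik(X, y, term, 0.0, tol, max_iter)
        lr = max(0.0, 2.0 * (ll - ll0))
        p = float(stats.chi2.sf(lr, 1))
    elif pvalue_method == "wald":
        p = float(2 * stats.norm.sf(abs(beta[term] / se[term])))
    else:
        raise ValueError("pvalue_method must be 'lrt' or 'wald'")

    if ci_method == "profile":
        lo, hi = _profile_ci(X, y, term, beta, ll, se[term], alpha, tol, max_iter)
    elif ci_method == "wald":
        z = stats.norm.isf(alpha / 2)
        lo, hi = beta[term] - z * se[term], beta[term] + z * se[term]
    else:
        raise ValueError("ci_method must be 'profile' or 'wald'")

    return FirthFit(
        coefficients=beta, standard_errors=se, odds_ratio=float(np.exp(beta[term])),
        p_value=p, ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        converged=converged, iterations=it, loglik=ll, term=term, columns=tuple(columns),
    )


def _profile_loglik(X, y, term, value, tol, max_iter) -> float:
    """Penalised log-likelihood maximised with ``beta[term]`` fixed at ``value``."""
    k = X.shape[1]
    free = np.ones(k, dtype=bool)
    free[term] = False
    beta0 = np.zeros(k)
    beta0[term] = value
    _, ll, _, _, _ = _firth_newton(X, y, free, beta0, tol=tol, max_iter=max_iter)
    return ll


def _profile_ci(X, y, term, beta, ll_max, se, alpha, tol, max_iter):
    """Profile-penalised-likelihood confidence bounds for one coefficient."""
    target = ll_max - stats.chi2.isf(alpha, 1) / 2.0
    b = beta[term]

    def deficit(v):
        return _profile_loglik(X, y, term, v, tol, max_iter) - target

    bounds = []
    for sign in (-1.0, +1.0):
        step = max(se, 0.25)
        lo_v, hi_v = b, b + sign * step
        for _ in range(60):
            if deficit(hi_v) < 0:
                break
            lo_v, hi_v = hi_v, hi_v + sign * step
            step *= 1.6
        else:
            bounds.append(np.inf * sign)
            continue
        lo_b, hi_b = (hi_v, lo_v) if sign < 0 else (lo_v, hi_v)
        root = optimize.brentq(deficit, lo_b, hi_b, xtol=1e-6)
        bounds.append(root)
    return min(bounds), max(bounds)


def build_design(phenotype: pd.Series, burden: pd.Series, pcs: pd.DataFrame,
                 baseline: pd.Series, extra: pd.DataFrame | None = None,
                 ) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Assemble (y, X, column names): intercept | burden | PCs | baseline [| extra]."""
    idx = phenotype.index
    parts = [pd.Series(1.0, index=idx, name="intercept"), burden.loc[idx]]
    parts += [pcs.loc[idx, c] for c in pcs.columns]
    parts.append(baseline.loc[idx])
    if extra is not None:
        parts += [extra.loc[idx, c] for c in extra.columns]
    M = pd.concat(parts, axis=1)
    # a covariate with no variation (e.g. a zero baseline count in a tiny
    # cohort) carries no information and would alias the intercept
    for c in M.columns[2:]:
        if M[c].nunique() == 1:
            logger.info("dropping constant covariate column %r", c)
            M = M.drop(columns=[c])
    return phenotype.to_numpy(dtype=float), M.to_numpy(dtype=float), tuple(M.columns)


def global_enrichment_test(cohort: CohortBundle, pcs: pd.DataFrame,
                           variant_class: str = "PTV", gene_set=None,
                           rare_config: RareVariantConfig | None = None,
                           stratified: bool = False,
                           ancestry_labels: pd.Series | None = None,
                           min_stratum_n: int = 100,
                           n_classes_tested: int = 5, alpha: float = 0.05,
                           extra_covariates: pd.DataFrame | None = None,
                           **fit_kwargs) -> pd.DataFrame:
    """Gene-set burden enrichment, ancestry-combined or stratified.

    Combined mode (default): rare = minor allele count <= 5, covariates are
    the first five global principal components plus the paired baseline
    burden. Stratified mode: rare = MAF < 0.1% within the stratum,
    covariates are the first four within-stratum components plus baseline;
    strata with fewer than ``min_stratum_n`` samples are skipped with a log
    entry. Returns one report row per fitted stratum with OR, 95% CI, p and
    a Bonferroni significance flag at ``alpha / n_classes_tested``.
    """
    if gene_set is None:
        gene_set = set(cohort.panel.index[cohort.panel["constrained"]])
    if rare_config is None:
        rare_config = RareVariantConfig(mode="maf" if stratified else "mac")
    n_pcs = 4 if stratified else 5
    base_cls = baseline_class(variant_class)

    def one(sub: CohortBundle, sub_pcs: pd.DataFrame, label: str) -> dict:
        burden = count_rare_burden(sub, gene_set, variant_class, rare_config)
        n_case = int((sub.samples["phenotype"] == 1).sum())
        n_control = int((sub.samples["phenotype"] == 0).sum())
        if burden.nunique() <= 1:
            logger.warning("burden of %s is constant in stratum %s; test undefined",
                           variant_class, label)
            return {"variant_class": variant_class, "ancestry": label,
                    "n_case": n_case, "n_control": n_control,
                    "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "n_variants": 0, "significant": False,
                    "converged": False}
        baseline = count_rare_burden(sub, set(sub.panel.index), base_cls, rare_config)
        baseline.name = f"baseline_{base_cls}"
        y, X, cols = build_design(sub.samples["phenotype"], burden,
                                  sub_pcs.iloc[:, :n_pcs], baseline, extra_covariates)
        fit = firth_logistic_fit(y, X, term=1, columns=cols, **fit_kwargs)
        n_var = int((sub.variants["gene"].isin(gene_set)
                     & sub.variants["variant_class"].isin(CLASS_MEMBERS[variant_class])).sum())
        return {
            "variant_class": variant_class, "ancestry": label,
            "n_case": int((sub.samples["phenotype"] == 1).sum()),
            "n_control": int((sub.samples["phenotype"] == 0).sum()),
            "odds_ratio": fit.odds_ratio, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
            "p_value": fit.p_value, "n_variants": n_var,
            "significant": fit.p_value < alpha / n_classes_tested,
            "converged": fit.converged,
        }

    rows = []
    if not stratified:
        rows.append(one(cohort, pcs, "ALL"))
    else:
        if ancestry_labels is None:
            raise ValueError("stratified mode needs ancestry labels")
        for pop in sorted(ancestry_labels.unique()):
            ids = ancestry_labels.index[ancestry_labels == pop]
            if len(ids) < min_stratum_n:
                logger.info("stratum %s skipped: n=%d < %d", pop, len(ids), min_stratum_n)
                continue
            sub = cohort.subset_samples(ids)
            from .ancestry import compute_pcs  # local import avoids cycle
            sub_pcs = compute_pcs(sub.dosages, sub.sample_ids, n_components=n_pcs).scores
            rows.append(one(sub, sub_pcs, pop))
    return pd.DataFrame(rows)
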