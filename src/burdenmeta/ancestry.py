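"""Genetic-ancestry assignment and principal-component covariates.

Cohort samples are placed in the principal-component space of LD-pruned
common SNPs computed jointly with a labelled reference panel (the five
continental super-populations AFR/AMR/EAS/EUR/SAS), then assigned to the
super-population holding the plurality among their K nearest reference
neighbours (default K=5 on the first three components, ties broken by the
single nearest neighbour). Within-population outliers are removed
iteratively — any sample more than ``n_sd`` standard deviations from the
mean on one of the top components — recomputing the components after each
round. The first five global components (or first four within-ancestry
components) serve as stratification covariates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import MISSING


@dataclass
class PCResult:
    """Principal-component scores and the variance each component explains."""

    scores: pd.DataFrame  # sample x component, columns PC1..PCk
    variance_explained: np.ndarray

    def top(self, k: int) -> pd.DataFrame:
        return self.scores.iloc[:, :k]


@dataclass
class AncestryModel:
    """Fitted reference space for KNN ancestry classification."""

    loadings: np.ndarray  # variant x component
    reference_coords: pd.DataFrame  # sample x component
    reference_labels: pd.Series
    k_neighbors: int = 5
    n_components_for_knn: int = 3


def _impute_standardize(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and standardise columns; drops nothing."""
    X = np.asarray(dosages, dtype=float)
    X = np.where(X == MISSING, np.nan, X)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    return (X[:, keep] - mean[keep]) / sd[keep]


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    Z = _impute_standardize(X)
    r = (Z.T @ Z) / Z.shape[0]
    return r**2


def select_pca_snps(variants: pd.DataFrame, dosages: np.ndarray,
                    maf_min: float = 0.01, ld_r2_max: float = 0.2,
                    window: int = 50) -> list:
    """Pick LD-pruned common SNPs for principal-component analysis.

    Keeps biallelic SNPs (single-base ref and alt) with minor allele
    frequency strictly above ``maf_min``, then greedily prunes: walking the
    variants in order, a SNP is kept only if its dosage r-squared with every
    already-kept SNP inside the trailing ``window`` stays at or below
    ``ld_r2_max``.
    """
    dosages = np.asarray(dosages)
    is_snp = (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1)
    called = dosages != MISSING
    with np.errstate(invalid="ignore"):
        af = np.where(called, dosages, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1)
    maf = np.minimum(af, 1 - af)
    candidates = np.flatnonzero(is_snp.to_numpy() & (maf > maf_min))
    if candidates.size == 0:
        raise ValueError("no common SNPs survive the MAF filter")

    Z = _impute_standardize_full(dosages[:, candidates])
    n = Z.shape[0]
    kept: list[int] = []
    for j in range(candidates.size):
        recent = kept[-window:]
        ok = True
        if recent:
            r = (Z[:, recent].T @ Z[:, j]) / n
            if (r**2 > ld_r2_max).any():
                ok = False
        if ok:
            kept.append(j)
    if not kept:
        raise ValueError("no SNPs survive LD pruning")
    return list(variants.index[candidates[kept]])


def _impute_standardize_full(dosages: np.ndarray) -> np.ndarray:
    """Like :func:`_impute_standardize` but keeps constant columns (as zeros)."""
    X = np.asarray(dosages, dtype=float)
    X = np.where(X == MISSING, np.nan, X)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def compute_pcs(dosages: np.ndarray, sample_ids, n_components: int = 10) -> PCResult:
    """Principal components of the standardised genotype matrix.

    Missing dosages are mean-imputed per variant. Scores are the
    eigen-decomposition of the sample covariance of the standardised
    matrix; the sign convention makes each component's largest-magnitude
    loading positive, so results are fully deterministic.
    """
    Z = _impute_standardize(np.asarray(dosages))
    n, m = Z.shape
    if m == 0:
        raise ValueError("degenerate input: every variant is constant")
    k = min(n_components, n, m)
    if k < 1:
        raise ValueError("need at least one sample and one variant")
    if m <= n:
        # eigendecompose the m x m cross-product (cheaper than SVD when n >> m)
        import scipy.linalg

        C = Z.T @ Z
        vals, vecs = scipy.linalg.eigh(C, subset_by_index=(m - k, m - 1))
        order = np.argsort(vals)[::-1]
        S = np.sqrt(np.maximum(vals[order], 0.0))
        Vt = vecs[:, order].T
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.where(S > 0, (Z @ Vt.T) / S, 0.0)
    else:
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    eigvals = S**2 / (n - 1)
    total_var = (Z**2).sum() / (n - 1)
    scores = pd.DataFrame(U * S, index=pd.Index(sample_ids),
                          columns=[f"PC{i+1}" for i in range(k)])
    return PCResult(scores=scores, variance_explained=eigvals / total_var)


def knn_assign(model: AncestryModel, cohort_scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each cohort sample to a super-population by plurality KNN vote.

    Distances are Euclidean in the first ``n_components_for_knn`` components.
    A tied plurality is resolved by the label of the single nearest
    neighbour. Returns a DataFrame with ``assigned_pop`` plus per-population
    vote counts.
    """
    d = model.n_components_for_knn
    ref = model.reference_coords.iloc[:, :d].to_numpy()
    if len(ref) < model.k_neighbors:
        raise ValueError("reference panel smaller than k_neighbors")
    nn = NearestNeighbors(n_neighbors=model.k_neighbors).fit(ref)
    _, idx = nn.kneighbors(cohort_scores.iloc[:, :d].to_numpy())
    labels = model.reference_labels.to_numpy()
    pops = sorted(pd.unique(labels))
    out = []
    for row in idx:
        votes = pd.Series(labels[row]).value_counts()
        top = votes[votes == votes.max()].index
        if len(top) == 1:
            pick = top[0]
        else:
            pick = labels[row[0]]  # nearest neighbour breaks the tie
        out.append({"assigned_pop": pick,
                    **{f"votes_{p}": int(votes.get(p, 0)) for p in pops}})
    return pd.DataFrame(out, index=cohort_scores.index)


def remove_pc_outliers(dosages: np.ndarray, sample_ids, n_sd: float = 6.0,
                       max_rounds: int = 5, n_components: int = 4,
                       ) -> tuple[pd.Index, list]:
    """Iteratively drop principal-component outliers within a population.

    Each round computes components on the current samples and removes any
    sample lying more than ``n_sd`` standard deviations from the mean on any
    of the top ``n_components`` components; stops when a round removes
    nobody or after ``max_rounds`` rounds. Returns (retained ids, list of
    removed-id lists per round).
    """
    ids = pd.Index(sample_ids)
    dosages = np.asarray(dosages)
    removed_per_round: list[list] = []
    current = np.arange(len(ids))
    for _ in range(max_rounds):
        if len(current) <= n_components:
            raise ValueError("too few samples left for outlier detection")
        pcs = compute_pcs(dosages[current], ids[current],
                          n_components=min(n_components, len(current) - 1))
        S = pcs.scores.to_numpy()
        sd = S.std(axis=0, ddof=0)
        sd[sd == 0] = np.inf
        dev = np.abs(S - S.mean(axis=0)) / sd
        bad = (dev > n_sd).any(axis=1)
        if not bad.any():
            break
        removed_per_round.append(list(ids[current[bad]]))
        current = current[~bad]
        if len(current) == 0:
            raise ValueError("outlier removal eliminated every sample")
    return ids[current], removed_per_round


def fit_joint_ancestry(ref_dosages: np.ndarray, ref_ids, ref_labels: pd.Series,
                       cohort_dosages: np.ndarray, cohort_ids,
                       n_components: int = 10, k_neighbors: int = 5,
                       n_components_for_knn: int = 3,
                       ) -> tuple[AncestryModel, PCResult, pd.DataFrame]:
    """Joint PCA of reference plus cohort, then KNN assignment of the cohort.

    Both genotype matrices must be column-aligned to the same SNP set.
    Returns the fitted model, the joint PC result, and the cohort
    assignment table.
    """
    if ref_dosages.shape[1] != cohort_dosages.shape[1]:
        raise ValueError("reference and cohort must share the SNP set")
    combined = np.vstack([ref_dosages, cohort_dosages])
    ids = list(ref_ids) + list(cohort_ids)
    pcs = compute_pcs(combined, ids, n_components=n_components)
    ref_coords = pcs.scores.iloc[: len(ref_ids)]
    cohort_coords = pcs.scores.iloc[len(ref_ids):]
    model = AncestryModel(
        loadings=np.empty(0),
        reference_coords=ref_coords,
        reference_labels=pd.Series(np.asarray(ref_labels), index=ref_coords.index),
        k_neighbors=k_neighbors,
        n_components_for_knn=n_components_for_knn,
    )
    assignments = knn_assign(model, cohort_coords)
    return model, pcs, assignments
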