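"""Discriminant analysis of principal components (DAPC).

Genotype dosages are mean-imputed, centred and decomposed by PCA; the
retained PC scores feed a linear discriminant analysis on predefined
groups, yielding at most n_groups - 1 discriminant functions.  The
alpha-score (observed correct-reassignment proportion minus its
permutation expectation) guides how many PCs to retain before the
discriminant step, trading discriminatory power against overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .datatypes import MISSING, GenotypeDataset


@dataclass
class PCAResult:
    scores: np.ndarray        # samples x PCs
    loadings: np.ndarray      # markers x PCs
    eigenvalues: np.ndarray
    explained: np.ndarray     # fraction of total variance per PC
    center: np.ndarray
    scale: np.ndarray


@dataclass
class DAPCResult:
    n_pcs: int
    df_loadings: np.ndarray      # PCs x DFs (linear combinations over PCs)
    coords: np.ndarray           # samples x DFs
    group_means: np.ndarray      # groups x DFs
    groups: list
    labels: np.ndarray           # per-sample group label
    posteriors: np.ndarray       # samples x groups, rows sum to 1
    eigenvalues: np.ndarray      # discriminant eigenvalues
    variance_represented: float  # explained var of retained PCs x discriminated share

    @property
    def n_df(self) -> int:
        return self.df_loadings.shape[1]

    @property
    def assignments(self) -> np.ndarray:
        return np.asarray(self.groups, dtype=object)[np.argmax(self.posteriors, axis=1)]

    def reassignment_accuracy(self) -> float:
        return float(np.mean(self.assignments == self.labels))


def impute_dosages(ds: GenotypeDataset) -> np.ndarray:
    """Dosage matrix as float with missing entries set to the marker mean."""
    X = ds.genotypes.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return X


def pca(ds: GenotypeDataset, n_components: int | None = None, scale: str = "none") -> PCAResult:
    """PCA of the imputed, column-centred dosage matrix via SVD.

    ``scale`` is ``none`` (covariance PCA), ``unit`` (correlation PCA), or
    ``allele_freq`` (divide by sqrt(p(1-p)), the drift-scaled convention).
    Sign convention: each PC's largest-magnitude loading is positive.
    """
    X = impute_dosages(ds)
    center = X.mean(axis=0)
    Xc = X - center
    if scale == "none":
        sd = np.ones(X.shape[1])
    elif scale == "unit":
        sd = Xc.std(axis=0, ddof=1)
    elif scale == "allele_freq":
        p = center / 2.0
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    sd = np.where(sd <= 0, 1.0, sd)
    Xs = Xc / sd
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; truncating")
        n_components = rank
    eigvals = s**2 / (X.shape[0] - 1)
    total_var = eigvals.sum()
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(rank):
        jmax = np.argmax(np.abs(vt[k]))
        if vt[k, jmax] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(
        scores=scores,
        loadings=vt[:n_components].T,
        eigenvalues=eigvals[:n_components],
        explained=eigvals[:n_components] / total_var if total_var > 0 else eigvals[:n_components],
        center=center,
        scale=sd,
    )


def n_pcs_for_variance(pca_res: PCAResult, target: float = 0.95) -> int:
    """Smallest number of leading PCs whose explained fractions reach ``target``."""
    cum = np.cumsum(pca_res.explained)
    idx = np.searchsorted(cum, target)
    return int(min(idx + 1, len(cum)))


def _lda(scores: np.ndarray, labels: np.ndarray, n_df: int | None, ridge: float = 1e-8):
    """LDA via within-class whitening then between-class eigendecomposition."""
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("discriminant analysis needs at least two groups")
    n, p = scores.shape
    grand = scores.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = {}
    for g in groups:
        sub = scores[labels == g]
        mu = sub.mean(axis=0)
        means[g] = mu
        dev = sub - mu
        W += dev.T @ dev
        B += len(sub) * np.outer(mu - grand, mu - grand)
    W /= max(n - len(groups), 1)
    B /= max(len(groups) - 1, 1)
    # whiten W (ridge-regularised if singular)
    evals, evecs = linalg.eigh(W)
    if evals.min() <= ridge * max(evals.max(), 1.0):
        evals = evals + ridge * max(evals.max(), 1.0)
    white = evecs @ np.diag(evals**-0.5) @ evecs.T
    M = white @ B @ white
    bvals, bvecs = linalg.eigh(M)
    order = np.argsort(bvals)[::-1]
    max_df = len(groups) - 1
    n_df = max_df if n_df is None else min(n_df, max_df)
    bvals = np.clip(bvals[order[:n_df]], 0, None)
    A = white @ bvecs[:, order[:n_df]]  # p x n_df, maps scores to DF coords
    # sign convention as in pca
    for k in range(A.shape[1]):
        jmax = np.argmax(np.abs(A[:, k]))
        if A[jmax, k] < 0:
            A[:, k] *= -1
    return A, bvals, groups, means


def dapc_fit(
    pca_res: PCAResult,
    labels,
    n_pcs: int,
    n_df: int | None = None,
    ridge: float = 1e-8,
) -> DAPCResult:
    """Linear discriminant analysis on the ``n_pcs`` leading PC scores.

    Posterior group memberships come from a Gaussian class model in DF
    space with shared identity covariance (the within-class covariance is
    whitened by construction) and equal priors.
    """
    labels = np.asarray(labels, dtype=object)
    if n_pcs > pca_res.scores.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds available PCs ({pca_res.scores.shape[1]})")
    S = pca_res.scores[:, :n_pcs]
    A, bvals, groups, means = _lda(S, labels, n_df, ridge)
    coords = S @ A
    gm = np.vstack([means[g] @ A for g in groups])
    d2 = ((coords[:, None, :] - gm[None, :, :]) ** 2).sum(axis=2)
    log_post = -0.5 * d2
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    # share of discriminant variance retained relative to the full DF set
    full_A, full_vals, _, _ = _lda(S, labels, None, ridge)
    disc_share = bvals.sum() / full_vals.sum() if full_vals.sum() > 0 else 1.0
    var_rep = float(pca_res.explained[:n_pcs].sum() * disc_share)
    return DAPCResult(
        n_pcs=n_pcs,
        df_loadings=A,
        coords=coords,
        group_means=gm,
        groups=groups,
        labels=labels,
        posteriors=post,
        eigenvalues=bvals,
        variance_represented=var_rep,
    )


def a_score(
    ds: GenotypeDataset,
    labels,
    candidate_n_pcs,
    n_permutations: int = 25,
    seed: int | None = None,
    pca_res: PCAResult | None = None,
) -> tuple[pd.DataFrame, int]:
    """Alpha-score per candidate PC count; returns (table, recommended n_pcs).

    alpha(n) = observed per-group correct-reassignment proportion minus the
    mean proportion under random relabelling, averaged over groups.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    if pca_res is None:
        pca_res = pca(ds)
    rows = []
    for n_pcs in candidate_n_pcs:
        if not 1 <= n_pcs < ds.n_samples:
            raise ValueError(f"candidate n_pcs {n_pcs} out of range")
        n_pcs_eff = min(n_pcs, pca_res.scores.shape[1])
        obs = _mean_group_accuracy(pca_res, labels, n_pcs_eff)
        null = np.mean(
            [
                _mean_group_accuracy(pca_res, rng.permutation(labels), n_pcs_eff)
                for _ in range(n_permutations)
            ]
        )
        rows.append((n_pcs, obs, null, obs - null))
    table = pd.DataFrame(rows, columns=["n_pcs", "observed", "null_mean", "a_score"])
    best = int(table.loc[table["a_score"].idxmax(), "n_pcs"])
    return table, best


def _mean_group_accuracy(pca_res: PCAResult, labels: np.ndarray, n_pcs: int) -> float:
    fit = dapc_fit(pca_res, labels, n_pcs)
    acc = []
    for g in fit.groups:
        mask = labels == g
        acc.append(float(np.mean(fit.assignments[mask] == g)))
    return float(np.mean(acc))
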