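"""Maximum-likelihood admixture estimation and Evanno delta-K selection.

Model: each individual i draws each of its two allele copies at locus j
from cluster k with probability q_ik, and the copy is the counted allele
with probability f_kj.  The genotype likelihood is Binomial(2, pi_ij)
with pi_ij = sum_k q_ik f_kj.  Q and P are estimated by EM from a seeded
random start (expected ancestry-allele counts, as in frappe/ADMIXTURE);
the log-likelihood is non-decreasing across iterations.  Replicate runs
over a range of K feed the Evanno delta-K criterion:

    deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD_K

with SD_K the standard deviation of the final log-likelihood across
replicates at K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeDataset

EPS = 1e-6


@dataclass
class AdmixtureRun:
    K: int
    seed: int | None
    loglik_trace: list
    Q: np.ndarray  # samples x K, rows sum to 1
    P: np.ndarray  # K x markers, in [EPS, 1-EPS]
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _prep(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    G = ds.genotypes.astype(float)
    obs = G != MISSING
    G[~obs] = 0.0
    return G, obs


def admixture_loglik(ds: GenotypeDataset, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial log-likelihood of the genotypes under (Q, P); missing
    genotypes are skipped.  pi values are clamped to [EPS, 1-EPS]."""
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    if Q.shape[0] != ds.n_samples or P.shape[1] != ds.n_markers or Q.shape[1] != P.shape[0]:
        raise ValueError("inconsistent Q/P dimensions")
    G, obs = _prep(ds)
    pi = np.clip(Q @ P, EPS, 1 - EPS)
    const = gammaln(3) - gammaln(G + 1) - gammaln(2 - G + 1)  # ln C(2, g)
    ll = G * np.log(pi) + (2 - G) * np.log1p(-pi) + const
    return float(ll[obs].sum())


def fit_admixture(
    ds: GenotypeDataset,
    K: int,
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureRun:
    """EM point estimation of the K-cluster admixture model.

    K=1 has the closed-form solution (Q all ones, P the pooled sample
    frequencies) and returns immediately.  For K>1, Q starts from a
    Dirichlet draw and P from frequency-perturbed pooled frequencies;
    convergence is declared when the log-likelihood gain drops below
    ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G, obs = _prep(ds)
    n, m = G.shape
    n_called = obs.sum(axis=0)
    pooled = np.divide(
        (G * obs).sum(axis=0), 2 * np.maximum(n_called, 1),
        out=np.full(m, 0.5), where=n_called > 0,
    )
    pooled = np.clip(pooled, EPS, 1 - EPS)
    if K == 1:
        Q = np.ones((n, 1))
        P = pooled[None, :]
        ll = admixture_loglik(ds, Q, P)
        return AdmixtureRun(1, seed, [ll], Q, P, True)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(pooled[None, :] + rng.uniform(-0.1, 0.1, size=(K, m)), EPS, 1 - EPS)
    miss = ~obs
    m_per_sample = obs.sum(axis=1)

    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        pi = np.clip(Q @ P, EPS, 1 - EPS)
        # E-step: expected counted / other allele copies from cluster k
        Qnew = np.empty_like(Q)
        P_num = np.empty_like(P)
        P_den = np.empty_like(P)
        for k in range(K):
            qf = Q[:, k : k + 1] * P[k][None, :]
            q1f = Q[:, k : k + 1] * (1 - P[k])[None, :]
            EA = G * qf / pi            # expected A1 copies from k
            EB = (2 - G) * q1f / (1 - pi)
            EA[miss] = 0.0
            EB[miss] = 0.0
            Qnew[:, k] = (EA + EB).sum(axis=1)
            P_num[k] = EA.sum(axis=0)
            P_den[k] = (EA + EB).sum(axis=0)
        Qnew /= (2 * np.maximum(m_per_sample, 1))[:, None]
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        Pnew = np.divide(P_num, P_den, out=np.full_like(P_num, 0.5), where=P_den > 0)
        Q, P = Qnew, np.clip(Pnew, EPS, 1 - EPS)
        ll = admixture_loglik(ds, Q, P)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at K={K}")
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return AdmixtureRun(K, seed, trace, Q, P, converged)


def run_replicates(
    ds: GenotypeDataset,
    k_values,
    n_replicates: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> list[AdmixtureRun]:
    """Replicate EM runs across a K range with derived per-run seeds."""
    rng = np.random.default_rng(seed)
    runs = []
    for K in k_values:
        for _ in range(n_replicates):
            runs.append(fit_admixture(ds, K, int(rng.integers(2**31)), max_iter, tol))
    return runs


def evanno_delta_k(runs: list[AdmixtureRun]) -> tuple[pd.DataFrame, int]:
    """Evanno table (mean L, L', L'', deltaK per K) and the selected K.

    Needs at least three consecutive K values with >=2 replicates each; a
    zero replicate SD yields an infinite (flagged) deltaK.  The selected K
    maximises deltaK over interior K values.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.loglik)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >=3 consecutive K values")
    mean_l = {k: float(np.mean(by_k[k])) for k in ks}
    sd_l = {k: float(np.std(by_k[k], ddof=1)) if len(by_k[k]) > 1 else np.nan for k in ks}
    rows = []
    for k in ks:
        lp = mean_l[k] - mean_l[k - 1] if k - 1 in mean_l else np.nan
        if k - 1 in mean_l and k + 1 in mean_l:
            lpp = abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1])
            dk = lpp / sd_l[k] if sd_l[k] and sd_l[k] > 0 else np.inf
        else:
            lpp, dk = np.nan, np.nan
        rows.append((k, len(by_k[k]), mean_l[k], sd_l[k], lp, lpp, dk))
    table = pd.DataFrame(
        rows, columns=["K", "n_replicates", "mean_loglik", "sd_loglik", "l_prime", "l_dblprime", "delta_k"]
    )
    interior = table.dropna(subset=["delta_k"])
    if interior.empty:
        raise ValueError("no interior K with a defined deltaK")
    selected = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return table, selected


def align_clusters(Q: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute columns of Q to best match a reference Q (greedy matching),
    resolving EM label switching before any truth comparison."""
    K = Q.shape[1]
    cost = np.array([[np.abs(Q[:, a] - reference[:, b]).sum() for b in range(K)] for a in range(K)])
    perm = [-1] * K
    used = set()
    for a in np.argsort(cost.min(axis=1)):
        b = min((b for b in range(K) if b not in used), key=lambda b: cost[a, b])
        perm[b] = a
        used.add(b)
    return Q[:, perm]


def admixture_by_group(Q: np.ndarray, groups, group_order=None) -> pd.DataFrame:
    """Per-group mean ancestry per cluster, clusters named by majority group.

    Rows (groups) sum to 1.  Each cluster is labelled after the group with
    the highest mean membership; when two clusters claim the same group
    the later one gets a numeric suffix.
    """
    groups = np.asarray(groups, dtype=object)
    labels = list(group_order) if group_order is not None else list(pd.unique(groups))
    means = np.vstack([Q[groups == g].mean(axis=0) for g in labels])
    K = Q.shape[1]
    cluster_names = []
    claimed: dict[str, int] = {}
    for k in range(K):
        g = labels[int(np.argmax(means[:, k]))]
        if g in claimed:
            claimed[g] += 1
            cluster_names.append(f"{g}_{claimed[g]}")
        else:
            claimed[g] = 1
            cluster_names.append(str(g))
    return pd.DataFrame(means, index=labels, columns=cluster_names)
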