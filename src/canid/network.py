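"""Pairwise allele-sharing distances and mutual k-nearest-neighbour graphs.

The default pairwise distance is 1 - IBS, where IBS similarity between two
samples is the mean over shared non-missing loci of (2 - |g_a - g_b|) / 2.
A PLINK-style method-of-moments PI_HAT (P(IBD=1)/2 + P(IBD=2), from the
IBS0/1/2 counts and sample allele frequencies) is available as an
alternative, with distance 1 - PI_HAT.  The mutual k-NN graph keeps an
edge (a, b) iff each sample is among the other's k nearest neighbours;
ties at the k-th distance are broken by sample order, so the graph is
fully deterministic.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .datatypes import MISSING, DistanceMatrix, GenotypeDataset


def ibs_distance_matrix(ds: GenotypeDataset, method: str = "ibs") -> DistanceMatrix:
    """Pairwise distance matrix between samples (``ibs`` or ``pi_hat``)."""
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    if method == "ibs":
        sim = _ibs_similarity(ds)
    elif method == "pi_hat":
        sim = _pi_hat(ds)
    else:
        raise ValueError(f"unknown method {method!r}")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ds.samples["sample_id"].tolist(), d, method)


def _ibs_similarity(ds: GenotypeDataset) -> np.ndarray:
    G = ds.genotypes.astype(float)
    obs = G != MISSING
    G[~obs] = 0.0
    n = ds.n_samples
    sim = np.ones((n, n))
    for i in range(n):
        both = obs[i][None, :] & obs[i:]
        diff = np.abs(G[i][None, :] - G[i:]) * both
        shared = both.sum(axis=1)
        if np.any(shared == 0):
            bad = np.flatnonzero(shared == 0) + i
            sim[i, bad] = sim[bad, i] = np.nan
        with np.errstate(invalid="ignore"):
            s = 1.0 - diff.sum(axis=1) / (2.0 * np.maximum(shared, 1))
        s = np.where(shared > 0, s, np.nan)
        sim[i, i:] = s
        sim[i:, i] = s
    return sim


def _pi_hat(ds: GenotypeDataset) -> np.ndarray:
    """Method-of-moments PI_HAT per pair (no small-sample correction).

    Per-locus conditional IBS-state expectations given IBD state use the
    sample allele frequencies; P(IBD=0/1/2) are solved by moments from the
    observed genome-wide IBS0/1/2 counts, clipped to [0, 1] and
    renormalised.
    """
    G = ds.genotypes.astype(float)
    obs = G != MISSING
    n_called = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, (np.where(obs, G, 0)).sum(axis=0) / (2 * np.maximum(n_called, 1)), np.nan)
    q = 1 - p
    # expected per-locus IBS-state probabilities conditional on IBD state
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2
    n = ds.n_samples
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j] & ~np.isnan(p)
            if not both.any():
                sim[i, j] = sim[j, i] = np.nan
                continue
            diff = np.abs(G[i, both] - G[j, both])
            ibs0 = float((diff == 2).sum())
            ibs1 = float((diff == 1).sum())
            ibs2 = float((diff == 0).sum())
            L = float(both.sum())
            s0 = e0_ibd0[both].sum()
            pi0 = ibs0 / s0 if s0 > 0 else 0.0
            s1 = e1_ibd1[both].sum()
            pi1 = (ibs1 - pi0 * e1_ibd0[both].sum()) / s1 if s1 > 0 else 0.0
            pi2 = (ibs2 - pi0 * e2_ibd0[both].sum() - pi1 * e2_ibd1[both].sum()) / L
            probs = np.clip([pi0, pi1, pi2], 0.0, 1.0)
            total = probs.sum()
            if total > 0:
                probs = probs / total
            sim[i, j] = sim[j, i] = probs[1] / 2 + probs[2]
    return sim


def knn_network(
    dist: DistanceMatrix,
    k: int,
    rule: str = "mutual",
    groups: dict | None = None,
) -> nx.Graph:
    """k-nearest-neighbour graph from a distance matrix.

    ``mutual`` keeps (a, b) iff each is in the other's k nearest;
    ``union`` keeps it if either is.  Ties at the k-th distance break by
    label position.  Node attribute ``group`` is set when provided.
    """
    n = len(dist.labels)
    if not 1 <= k < n:
        raise ValueError("require 1 <= k < n_samples")
    if rule not in ("mutual", "union"):
        raise ValueError(f"unknown rule {rule!r}")
    d = dist.values
    neighbour_sets = []
    idx = np.arange(n)
    for i in range(n):
        row = np.where(np.isnan(d[i]), np.inf, d[i]).copy()
        row[i] = np.inf
        order = np.lexsort((idx, row))  # distance, then label position
        neighbour_sets.append(set(order[:k].tolist()))
    g = nx.Graph(k=k, rule=rule, method=dist.method)
    for i, label in enumerate(dist.labels):
        g.add_node(label, group=groups.get(label) if groups else None)
    for i in range(n):
        for j in neighbour_sets[i]:
            if j <= i:
                continue
            keep = (i in neighbour_sets[j]) if rule == "mutual" else True
            if keep:
                g.add_edge(dist.labels[i], dist.labels[j], weight=float(d[i, j]))
        if rule == "union":
            for j in range(i + 1, n):
                if i in neighbour_sets[j]:
                    g.add_edge(dist.labels[i], dist.labels[j], weight=float(d[i, j]))
    return g


def within_group_edge_fraction(g: nx.Graph) -> float:
    """Fraction of edges joining two nodes of the same group."""
    edges = list(g.edges)
    if not edges:
        return float("nan")
    same = sum(1 for a, b in edges if g.nodes[a]["group"] == g.nodes[b]["group"])
    return same / len(edges)


def edge_table(g: nx.Graph):
    import pandas as pd

    rows = [(a, b, data.get("weight")) for a, b, data in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance"]).sort_values(
        ["sample_a", "sample_b"]
    ).reset_index(drop=True)
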