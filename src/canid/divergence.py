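"""Population differentiation: allele frequencies, Nei distances, W&C F_ST.

Nei's 1972 standard distance is D = -ln(J_xy / sqrt(J_x J_y)) with gene
identities pooled over loci before the ratio; Nei's 1983 D_A is
1 - (1/L) sum_loci sum_alleles sqrt(x y).  F_ST between pairs of groups is
the Weir & Cockerham (1984) theta estimator built from per-locus variance
components a (among populations), b (among individuals within populations)
and c (within individuals), using observed heterozygosity from the
genotype calls: theta = sum(a) / sum(a + b + c) over loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, DistanceMatrix, GenotypeDataset

#: Flag value returned for an infinite Nei-1972 distance (zero identity).
NEI_INF = 1e6


@dataclass
class AlleleFreqTable:
    """Per-group A1 frequencies and non-missing allele counts (2 x genotyped)."""

    groups: list
    marker_ids: list
    freqs: np.ndarray   # groups x markers, NaN when no genotyped sample
    counts: np.ndarray  # groups x markers, allele counts

    def row(self, group) -> np.ndarray:
        return self.freqs[self.groups.index(group)]


def allele_freqs(ds: GenotypeDataset, by: str | None = "group") -> AlleleFreqTable:
    """A1 allele frequency per group per marker, missing calls excluded.

    ``by=None`` treats each sample as its own unit (frequencies in
    {0, 0.5, 1}), the convention for individual-level Nei matrices.
    """
    if by == "group":
        labels = list(pd.unique(ds.samples["group"]))
        membership = [ds.samples.index[ds.samples["group"] == g].to_numpy() for g in labels]
    elif by is None:
        labels = ds.samples["sample_id"].tolist()
        membership = [np.array([i]) for i in range(ds.n_samples)]
    else:
        raise ValueError(f"unknown grouping {by!r}")
    ng, m = len(labels), ds.n_markers
    freqs = np.full((ng, m), np.nan)
    counts = np.zeros((ng, m))
    for k, idx in enumerate(membership):
        g = ds.genotypes[idx]
        called = g != MISSING
        n_alleles = 2 * called.sum(axis=0)
        dose = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(n_alleles > 0, dose / np.maximum(n_alleles, 1), np.nan)
        counts[k] = n_alleles
    return AlleleFreqTable(labels, ds.markers["marker_id"].tolist(), freqs, counts)


# ---------------------------------------------------------------------------
# Nei distances
# ---------------------------------------------------------------------------

def _nei_pair(p1: np.ndarray, p2: np.ndarray, method: str) -> float:
    ok = ~(np.isnan(p1) | np.isnan(p2))
    p1, p2 = p1[ok], p2[ok]
    if p1.size == 0:
        return math.nan
    q1, q2 = 1 - p1, 1 - p2
    if method == "nei1972":
        jxy = float(np.sum(p1 * p2 + q1 * q2))
        jx = float(np.sum(p1**2 + q1**2))
        jy = float(np.sum(p2**2 + q2**2))
        identity = jxy / math.sqrt(jx * jy)
        if identity <= 0:
            return NEI_INF
        return -math.log(identity)
    if method == "nei1983":
        return float(1.0 - np.mean(np.sqrt(p1 * p2) + np.sqrt(q1 * q2)))
    raise ValueError(f"unknown Nei method {method!r}")


def nei_distance(freqs: AlleleFreqTable, method: str = "nei1972") -> DistanceMatrix:
    """Pairwise Nei distance between frequency units (groups or individuals).

    Loci with a missing frequency in either unit are skipped pairwise.  A
    zero identity under nei1972 (fully fixed opposite alleles) would be
    infinite and is returned as the flag value :data:`NEI_INF`.
    """
    n = len(freqs.groups)
    if n < 2:
        raise ValueError("need at least two units")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _nei_pair(freqs.freqs[i], freqs.freqs[j], method)
    return DistanceMatrix(list(freqs.groups), d, method)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-locus W&C (1984) variance components for r populations.

    n, p, h: (r, L) arrays of sample sizes, A1 frequencies and observed
    heterozygote proportions.  Returns (a, b, c) each of shape (L,).
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    total = n.sum(axis=0)
    nc = (total - (n**2).sum(axis=0) / total) / (r - 1)
    pbar = (n * p).sum(axis=0) / total
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / total
    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_fst_pair(ds: GenotypeDataset, group_a: str, group_b: str) -> tuple[float, float]:
    """(theta, raw_theta) for one pair of groups; raw is unclipped."""
    dm = wc_fst_pairwise(ds, groups=[group_a, group_b])
    raw = dm.extras["raw"]
    return dm.pair(group_a, group_b), float(raw[0, 1])


def wc_fst_pairwise(
    ds: GenotypeDataset,
    groups: list | None = None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> DistanceMatrix:
    """Pairwise Weir-Cockerham theta between groups.

    Loci with no genotyped sample in either group are skipped; loci that
    are monomorphic across the pair contribute zero to both sums.  The
    headline matrix clips negative estimates to 0; unclipped values sit in
    ``extras["raw"]``.  With ``n_bootstrap`` > 0, percentile 95% CIs over
    loci are stored in ``extras["ci"]``.
    """
    labels = groups if groups is not None else list(pd.unique(ds.samples["group"]))
    for g in labels:
        if (ds.samples["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    G = ds.genotypes
    stats = {}
    for g in labels:
        idx = ds.samples.index[ds.samples["group"] == g].to_numpy()
        sub = G[idx]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        dose = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, dose / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0, (sub == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        stats[g] = (n, p, h)
    k = len(labels)
    theta = np.zeros((k, k))
    raw = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    ci = {}
    for i in range(k):
        for j in range(i + 1, k):
            (na, pa, ha), (nb, pb, hb) = stats[labels[i]], stats[labels[j]]
            ok = (na > 0) & (nb > 0) & (na + nb > 2) & ~np.isnan(pa) & ~np.isnan(pb)
            n2 = np.stack([na[ok], nb[ok]])
            p2 = np.stack([pa[ok], pb[ok]])
            h2 = np.stack([ha[ok], hb[ok]])
            a, b, c = _wc_components(n2, p2, h2)
            denom = (a + b + c).sum()
            if denom == 0:
                raw[i, j] = raw[j, i] = math.nan
                theta[i, j] = theta[j, i] = math.nan
                continue
            t = a.sum() / denom
            raw[i, j] = raw[j, i] = t
            theta[i, j] = theta[j, i] = max(t, 0.0)
            if n_bootstrap > 0:
                L = a.size
                reps = []
                for _ in range(n_bootstrap):
                    sel = rng.integers(0, L, L)
                    d = (a[sel] + b[sel] + c[sel]).sum()
                    reps.append(a[sel].sum() / d if d else math.nan)
                ci[(labels[i], labels[j])] = tuple(np.nanpercentile(reps, [2.5, 97.5]))
    extras = {"raw": raw}
    if n_bootstrap > 0:
        extras["ci"] = ci
    return DistanceMatrix(list(labels), theta, "fst_wc", extras)


def summarize_vs_group(matrix: DistanceMatrix, focal: str) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the focal unit's off-diagonal entries."""
    if focal not in matrix.labels:
        raise ValueError(f"{focal!r} not in matrix labels")
    i = matrix.labels.index(focal)
    others = np.array([matrix.values[i, j] for j in range(len(matrix.labels)) if j != i])
    others = others[~np.isnan(others)]
    if others.size < 2:
        raise ValueError("need at least two partners to summarise")
    return float(others.mean()), float(others.std(ddof=1))


def combined_table(fst: DistanceMatrix, nei: DistanceMatrix) -> pd.DataFrame:
    """One square table with F_ST below the diagonal and Nei distance above."""
    if fst.labels != nei.labels:
        raise ValueError("matrices have different labels")
    n = len(fst.labels)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i > j:
                out[i, j] = fst.values[i, j]
            elif i < j:
                out[i, j] = nei.values[i, j]
    return pd.DataFrame(out, index=fst.labels, columns=fst.labels)
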