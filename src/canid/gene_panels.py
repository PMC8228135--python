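"""Candidate-gene panels: SNP-in-gene subsetting, panel PCA and factor analysis.

Panels group gene intervals into four phenotype categories: aerobic
trainability (ATO), behaviour and motivation (BM), coat colour (CC), and
strength and endurance (SE).  A SNP belongs to a gene iff its chromosome
matches and start <= position <= end (closed interval, both edges in).
Panel-wise stratification uses PCA on the subset dosages and principal-axis
factor analysis (optionally varimax-rotated), with each gene treated as a
candidate latent factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset
from . import dapc

CATEGORIES = ("ATO", "BM", "CC", "SE")
PANEL_COLUMNS = ["chromosome", "start_bp", "end_bp", "gene", "category"]


def load_panel(path=None) -> pd.DataFrame:
    """Read a BED-like panel TSV (chrom, start, end, gene, category).

    Without a path, loads the packaged example panel: the candidate genes
    for the four phenotype categories with synthetic placeholder
    coordinates laid out on the default simulated genome (real-genome
    coordinates are user-supplied).
    """
    if path is None:
        ref = resources.files("canid").joinpath("data/synthetic_panel.tsv")
        with resources.as_file(ref) as p:
            panel = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    else:
        panel = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel file lacks columns: {sorted(missing)}")
    bad = panel["start_bp"] > panel["end_bp"]
    if bad.any():
        raise ValueError(f"{bad.sum()} panel intervals have start > end")
    unknown = set(panel["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}; expected {CATEGORIES}")
    return panel


def map_snps_to_genes(
    markers: pd.DataFrame, panel: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Assign SNPs to gene intervals and collect per-category marker subsets.

    Returns an assignment table (marker_id, gene, category; one row per
    hit, so a SNP inside overlapping genes appears once per gene) and a
    dict category -> sorted array of marker column indices.
    """
    chrom = markers["chromosome"].to_numpy()
    pos = markers["position"].to_numpy()
    hits = []
    for row in panel.itertuples(index=False):
        inside = (chrom == row.chromosome) & (pos >= row.start_bp) & (pos <= row.end_bp)
        for j in np.flatnonzero(inside):
            hits.append((markers["marker_id"].iloc[j], j, row.gene, row.category))
    assignment = pd.DataFrame(hits, columns=["marker_id", "marker_index", "gene", "category"])
    multi = assignment["marker_id"].duplicated(keep=False)
    if multi.any():
        warnings.warn(
            f"{assignment.loc[multi, 'marker_id'].nunique()} SNPs fall in overlapping genes; "
            "assigned to all"
        )
    subsets: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        idx = np.unique(assignment.loc[assignment["category"] == cat, "marker_index"].to_numpy())
        if idx.size == 0:
            warnings.warn(f"category {cat} has no SNPs in any gene; skipped")
            continue
        subsets[cat] = idx
    return assignment, subsets


def panel_pca(ds: GenotypeDataset, subset: np.ndarray, **kwargs) -> dapc.PCAResult:
    """PCA restricted to the panel's marker columns (delegates to dapc.pca)."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty marker subset")
    return dapc.pca(ds.subset_markers(subset), **kwargs)


@dataclass
class FactorResult:
    loadings: pd.DataFrame      # variables x factors
    scores: np.ndarray          # samples x factors (regression scores)
    communalities: pd.Series
    rotation: str
    variables: list


def factor_analysis(
    ds: GenotypeDataset,
    subset: np.ndarray,
    n_factors: int,
    rotation: str = "varimax",
    aggregate_by_gene: pd.DataFrame | None = None,
    max_iter: int = 100,
) -> FactorResult:
    """Principal-axis factor analysis of panel dosages.

    Variables are the standardised marker dosages, or per-gene mean
    dosages when ``aggregate_by_gene`` (an assignment table from
    :func:`map_snps_to_genes`) is given — the "one gene, one factor"
    reading uses the aggregated mode with ``n_factors = n_genes``.
    Rotation is ``none`` or ``varimax``; varimax preserves the total
    communality.  Factor scores are Thomson regression scores.
    """
    from statsmodels.multivariate.factor import Factor

    X = dapc.impute_dosages(ds.subset_markers(np.asarray(subset)))
    if aggregate_by_gene is not None:
        sub = aggregate_by_gene[aggregate_by_gene["marker_index"].isin(np.asarray(subset))]
        genes = list(pd.unique(sub["gene"]))
        lookup = {int(j): k for k, j in enumerate(np.asarray(subset))}
        cols = []
        for gene in genes:
            jj = [lookup[int(j)] for j in sub.loc[sub["gene"] == gene, "marker_index"]]
            cols.append(X[:, jj].mean(axis=1))
        X = np.column_stack(cols)
        names = genes
    else:
        names = ds.markers["marker_id"].iloc[np.asarray(subset)].tolist()
    if n_factors > X.shape[1]:
        raise ValueError(f"n_factors={n_factors} exceeds {X.shape[1]} variables")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} constant variables dropped before factoring")
        X = X[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        n_factors = min(n_factors, X.shape[1])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    model = Factor(endog=Z, n_factor=n_factors, method="pa")
    try:
        res = model.fit(maxiter=max_iter)
    except Exception as exc:  # non-convergent communalities
        raise RuntimeError(f"principal-axis factoring failed: {exc}") from exc
    L = np.asarray(res.loadings)
    if rotation == "varimax":
        res.rotate("varimax")
        L = np.asarray(res.loadings)
    elif rotation != "none":
        raise ValueError(f"unknown rotation {rotation!r}")
    communalities = np.clip((L**2).sum(axis=1), 0, 1)
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    R_inv = np.linalg.pinv(R + 1e-10 * np.eye(R.shape[0]))
    scores = Z @ R_inv @ L
    factor_names = [f"F{k + 1}" for k in range(L.shape[1])]
    return FactorResult(
        loadings=pd.DataFrame(L, index=names, columns=factor_names),
        scores=scores,
        communalities=pd.Series(communalities, index=names),
        rotation=rotation,
        variables=names,
    )
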