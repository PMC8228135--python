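"""Core containers shared by every stage of the pipeline.

A :class:`GenotypeDataset` holds biallelic autosomal SNP genotypes as
counted-allele dosages (0/1/2, with ``-1`` for missing) in a samples x
markers ``int8`` matrix, together with a marker map and per-sample group
labels.  All downstream stages (ROH scan, divergence, DAPC, admixture,
network, gene panels) consume this one currency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Dog autosome labels; the autosome filter keeps these by default.
DOG_AUTOSOMES = tuple(str(c) for c in range(1, 39))

MARKER_COLUMNS = ["marker_id", "chromosome", "position", "a1", "a2"]
SAMPLE_COLUMNS = ["sample_id", "group"]


def _chrom_sort_key(labels: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering ('2' before '10', non-numeric last)."""
    num = pd.to_numeric(labels, errors="coerce")
    return num.fillna(np.inf)


@dataclass
class GenotypeDataset:
    """Samples x markers dosage matrix with marker map and sample table.

    Attributes
    ----------
    samples : pd.DataFrame
        Columns ``sample_id`` (unique) and ``group``.
    markers : pd.DataFrame
        Columns ``marker_id`` (unique), ``chromosome`` (string label),
        ``position`` (1-based bp), ``a1``/``a2`` (counted / other allele).
    genotypes : np.ndarray
        ``int8`` matrix of A1-allele dosages; ``-1`` encodes missing.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- basic facts -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def groups(self) -> np.ndarray:
        return self.samples["group"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def validate(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()]
            raise ValueError(f"duplicate marker ids: {sorted(set(dup))}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype values outside {{0,1,2,missing}}")

    # -- manipulation ------------------------------------------------
    def sorted_by_position(self) -> "GenotypeDataset":
        """Markers reordered by (chromosome, position), numeric-aware."""
        order = self.markers.assign(_k=_chrom_sort_key(self.markers["chromosome"])) \
            .sort_values(["_k", "chromosome", "position"], kind="mergesort").index
        return GenotypeDataset(
            self.samples,
            self.markers.loc[order],
            self.genotypes[:, np.asarray(order)],
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(self.samples, self.markers.iloc[index], self.genotypes[:, index])

    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(self.samples.iloc[index], self.markers, self.genotypes[index, :])

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.samples.copy(), self.markers.copy(), self.genotypes.copy())

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.markers.reset_index(drop=True).equals(other.markers.reset_index(drop=True))
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class QCReport:
    """Accounting for one filtering pass; ``in = out + removed`` on both axes."""

    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    thresholds: dict = field(default_factory=dict)
    removed: dict = field(default_factory=dict)  # filter name -> count

    def __post_init__(self) -> None:
        if self.n_markers_out > self.n_markers_in or self.n_samples_out > self.n_samples_in:
            raise ValueError("QCReport: more items out than in")

    @property
    def n_markers_removed(self) -> int:
        return self.n_markers_in - self.n_markers_out

    @property
    def n_samples_removed(self) -> int:
        return self.n_samples_in - self.n_samples_out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_markers_in": self.n_markers_in,
                "n_markers_out": self.n_markers_out,
                "n_samples_in": self.n_samples_in,
                "n_samples_out": self.n_samples_out,
                "thresholds": self.thresholds,
                "removed": self.removed,
            },
            indent=2,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("markers", self.n_markers_in, self.n_markers_out, self.n_markers_removed),
            ("samples", self.n_samples_in, self.n_samples_out, self.n_samples_removed),
        ]
        return pd.DataFrame(rows, columns=["axis", "n_in", "n_out", "n_removed"])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity with a method tag.

    ``method`` is one of ``fst_wc``, ``nei1972``, ``nei1983``, ``ibs``,
    ``pi_hat``.  ``extras`` may carry diagnostics such as unclipped FST
    values or bootstrap CIs.
    """

    labels: list
    values: np.ndarray
    method: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair(self, a, b) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])
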