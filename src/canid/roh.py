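"""Runs of homozygosity: detection, length classes, and genomic inbreeding.

A run of homozygosity (ROH) is a maximal stretch of consecutive homozygous
SNP genotypes on one chromosome.  Detection follows the consecutive-runs
criterion (as in detectRUNS' "consecutive" mode): a run is broken by any
heterozygous or missing genotype (when none are allowed) and by inter-SNP
gaps larger than ``max_gap_bp``; surviving runs must clear a minimum
physical length, a minimum SNP count, and a maximum average SNP spacing.

The genomic inbreeding coefficient F_ROH is the fraction of the
SNP-covered autosome lying in ROH.  Five coefficients are reported per
sample, one per length threshold (>=0.5, >=2, >=4, >=8, >=16 Mbp); the
default convention is cumulative (a 20 Mbp segment counts towards every
threshold it exceeds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset

MBP = 1_000_000

SEGMENT_COLUMNS = ["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"]

#: Length-class bounds in Mbp used throughout: (0-2, 2-4, 4-8, 8-16, >16).
DEFAULT_CLASS_BOUNDS = (0.0, 2.0, 4.0, 8.0, 16.0, math.inf)


@dataclass
class ROHParams:
    """Detection thresholds.  Defaults reproduce a 500 kb minimum length,
    1000 kb maximum gap, no heterozygous or missing calls inside a run,
    and at least one SNP per 5000 kb on average."""

    min_length_bp: int = 500_000
    max_gap_bp: int = 1_000_000
    max_het: int = 0
    max_missing: int = 0
    min_density_bp_per_snp: float = 5_000_000
    min_snps: int | None = None  # from lencz_min_snps when None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "max_gap_bp", "min_density_bp_per_snp", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("max_het / max_missing must be >= 0")


def lencz_min_snps(alpha: float, n_snps: int, n_samples: int, mean_het: float) -> int:
    """Minimum number of SNPs for a run to be called, controlling the
    proportion of false-positive ROH at ``alpha``:

        l = ln( alpha / (n_snps * n_samples) ) / ln(1 - mean_het)

    floored to an integer (minimum 1).  ``mean_het`` is the average
    heterozygosity across SNPs and samples.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_snps < 1 or n_samples < 1:
        raise ValueError("n_snps and n_samples must be >= 1")
    if not 0 < mean_het < 1:
        raise ValueError("mean_het must lie in (0, 1): log undefined otherwise")
    l = math.log(alpha / (n_snps * n_samples)) / math.log(1.0 - mean_het)
    return max(1, math.floor(l))


def mean_heterozygosity(ds: GenotypeDataset) -> float:
    """Observed heterozygote fraction over all non-missing genotype calls."""
    called = ds.genotypes != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("no called genotypes")
    return float((ds.genotypes == 1).sum() / n_called)


def _passes(start: int, end: int, n: int, params: ROHParams, min_snps: int) -> bool:
    length = end - start + 1
    return (
        length >= params.min_length_bp
        and n >= min_snps
        and length / n <= params.min_density_bp_per_snp
    )


def detect_roh(ds: GenotypeDataset, params: ROHParams | None = None) -> pd.DataFrame:
    """Scan every sample x chromosome for runs of homozygosity.

    Markers must be sorted by (chromosome, position).  Returns a segment
    table with columns sample_id, chromosome, start_bp, end_bp (positions
    of the first/last homozygous SNP, closed interval), n_snps, length_bp.

    When ``params.max_het``/``max_missing`` are positive the scan is a
    greedy left-to-right extension that admits up to that many offending
    calls per run (runs are trimmed back to homozygous endpoints); with
    the defaults (0/0) it is the exact maximal-run decomposition.
    """
    params = params or ROHParams()
    min_snps = params.min_snps
    if min_snps is None:
        min_snps = lencz_min_snps(
            params.alpha, ds.n_markers, ds.n_samples, mean_heterozygosity(ds)
        )

    chroms = ds.markers["chromosome"].to_numpy()
    pos = ds.markers["position"].to_numpy()
    # enforce sortedness
    for c in pd.unique(chroms):
        p = pos[chroms == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"markers on chromosome {c} are not position-sorted")

    records: list[tuple] = []
    sample_ids = ds.samples["sample_id"].to_numpy()
    for c in pd.unique(chroms):
        sel = chroms == c
        p = pos[sel]
        gap_break = np.zeros(len(p), dtype=bool)
        if len(p) > 1:
            gap_break[1:] = np.diff(p) > params.max_gap_bp
        G = ds.genotypes[:, sel]
        for i in range(ds.n_samples):
            g = G[i]
            records.extend(
                (sample_ids[i], c, s, e, n)
                for s, e, n in _scan_chromosome(g, p, gap_break, params, min_snps)
            )
    seg = pd.DataFrame(records, columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps"])
    seg["length_bp"] = seg["end_bp"] - seg["start_bp"] + 1 if len(seg) else pd.Series(dtype=int)
    return seg.reset_index(drop=True)[SEGMENT_COLUMNS] if len(seg) else pd.DataFrame(
        columns=SEGMENT_COLUMNS
    )


def _scan_chromosome(g, pos, gap_break, params: ROHParams, min_snps: int):
    """Yield (start_bp, end_bp, n_snps) for qualifying runs on one chromosome."""
    n = len(g)
    het_budget, miss_budget = params.max_het, params.max_missing
    out = []
    i = 0
    while i < n:
        if g[i] == 1 or g[i] == MISSING:
            i += 1
            continue
        # grow a run starting at homozygous SNP i
        hets = miss = 0
        members = [i]
        j = i + 1
        while j < n and not gap_break[j]:
            if g[j] == 1:
                if hets + 1 > het_budget:
                    break
                hets += 1
            elif g[j] == MISSING:
                if miss + 1 > miss_budget:
                    break
                miss += 1
            members.append(j)
            j = j + 1
        # trim to homozygous endpoints
        while members and g[members[-1]] in (1, MISSING):
            members.pop()
        homo = [k for k in members if g[k] not in (1, MISSING)]
        start, end, count = pos[members[0]], pos[members[-1]], len(homo)
        if _passes(start, end, count, params, min_snps):
            out.append((int(start), int(end), int(count)))
        i = members[-1] + 1 if members else i + 1
        i = max(i, j if (j < n and gap_break[j]) else i)
    return out


# ---------------------------------------------------------------------------
# length classes
# ---------------------------------------------------------------------------

@dataclass
class LengthClassScheme:
    """Contiguous ROH length classes in Mbp covering (0, inf)."""

    bounds_mbp: tuple = DEFAULT_CLASS_BOUNDS

    def __post_init__(self) -> None:
        b = self.bounds_mbp
        if b[0] != 0 or b[-1] != math.inf or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("class bounds must increase from 0 to inf")

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.bounds_mbp, self.bounds_mbp[1:]):
            out.append(f">{lo:g}" if math.isinf(hi) else f"{lo:g}-{hi:g}")
        return out

    def assign(self, length_bp: np.ndarray) -> np.ndarray:
        """Class label per segment; classes are (lo, hi] except the first,
        which also admits its lower edge."""
        mbp = np.asarray(length_bp, dtype=float) / MBP
        idx = np.searchsorted(self.bounds_mbp[1:-1], mbp, side="left")
        return np.asarray(self.labels, dtype=object)[idx]

    @property
    def lower_bounds_mbp(self) -> list[float]:
        return list(self.bounds_mbp[:-1])


def classify_roh(
    segments: pd.DataFrame,
    scheme: LengthClassScheme | None = None,
    groups: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label segments by length class and summarise per group.

    ``groups`` maps sample_id -> group; without it all samples form one
    group.  The summary has one row per (group, class): segment count,
    mean length in Mbp, and the class share of the group's segments in %.
    """
    scheme = scheme or LengthClassScheme()
    seg = segments.copy()
    seg["length_class"] = scheme.assign(seg["length_bp"].to_numpy()) if len(seg) else []
    if groups is None:
        seg["group"] = "all"
    else:
        mapping = groups if isinstance(groups, dict) else dict(groups)
        seg["group"] = seg["sample_id"].map(mapping)
    rows = []
    for grp, sub in seg.groupby("group", sort=False):
        total = len(sub)
        for label in scheme.labels:
            cls = sub[sub["length_class"] == label]
            rows.append(
                (
                    grp,
                    label,
                    len(cls),
                    cls["length_bp"].mean() / MBP if len(cls) else np.nan,
                    100.0 * len(cls) / total if total else np.nan,
                )
            )
    summary = pd.DataFrame(
        rows, columns=["group", "length_class", "n_roh", "mean_length_mbp", "share_pct"]
    )
    return seg, summary


def class_shares(counts) -> np.ndarray:
    """Distribution of ROH across classes, in percent of the total count."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("no segments to distribute")
    return 100.0 * counts / counts.sum()


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------

@dataclass
class FrohResult:
    """Per-sample inbreeding coefficients and per-group summaries."""

    per_sample: pd.DataFrame
    per_group: pd.DataFrame | None = None
    mode: str = "cumulative"
    thresholds_mbp: tuple = field(default_factory=tuple)


def froh(
    segments: pd.DataFrame,
    genome_length_bp: float,
    scheme: LengthClassScheme | None = None,
    samples: pd.DataFrame | None = None,
    mode: str = "cumulative",
) -> FrohResult:
    """Per-sample F_ROH at each length threshold.

    ``mode="cumulative"`` (default): froh_ge_X sums segments of length >= X
    Mbp.  ``mode="per_class"``: sums within the class [X, next bound) only.
    ``samples`` (sample_id + group) supplies zero rows for ROH-free samples
    and enables the per-group mean +/- SD (n-1 denominator) summary.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    scheme = scheme or LengthClassScheme()
    lows = scheme.lower_bounds_mbp
    if samples is not None:
        sample_ids = samples["sample_id"].tolist()
    else:
        sample_ids = sorted(segments["sample_id"].unique())
    cols = {"froh_total": []}
    for x in lows:
        cols[f"froh_ge_{x:g}"] = []
    bounds = list(scheme.bounds_mbp)
    for sid in sample_ids:
        lengths = segments.loc[segments["sample_id"] == sid, "length_bp"].to_numpy(dtype=float)
        cols["froh_total"].append(lengths.sum() / genome_length_bp)
        for k, x in enumerate(lows):
            if mode == "cumulative":
                mask = lengths >= x * MBP
            elif mode == "per_class":
                hi = bounds[k + 1]
                mask = (lengths >= x * MBP) & (lengths < hi * MBP)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            cols[f"froh_ge_{x:g}"].append(lengths[mask].sum() / genome_length_bp)
    per_sample = pd.DataFrame({"sample_id": sample_ids, **cols})
    per_group = None
    if samples is not None:
        merged = per_sample.merge(samples[["sample_id", "group"]], on="sample_id")
        value_cols = [c for c in per_sample.columns if c != "sample_id"]
        per_group = merged.groupby("group")[value_cols].agg(["mean", lambda s: s.std(ddof=1)])
        per_group.columns = [
            f"{c}_{'sd' if name == '<lambda_0>' else name}" for c, name in per_group.columns
        ]
        per_group = per_group.reset_index()
    return FrohResult(per_sample, per_group, mode, tuple(lows))


def froh_from_class_summary(
    counts,
    mean_lengths_mbp,
    n_animals: int,
    genome_length_mbp: float,
    lower_bounds_mbp=(0.0, 2.0, 4.0, 8.0, 16.0),
) -> np.ndarray:
    """Group-mean cumulative F_ROH (in %) reconstructed from a per-class
    summary (segment counts and mean lengths in Mbp, classes in ascending
    length order).  Entry k is the mean F_ROH over segments with length
    >= lower bound k, averaged over ``n_animals``.
    """
    counts = np.asarray(counts, dtype=float)
    mean_lengths_mbp = np.asarray(mean_lengths_mbp, dtype=float)
    total_len = counts * mean_lengths_mbp  # Mbp per class, summed over animals
    out = []
    for k in range(len(lower_bounds_mbp)):
        out.append(100.0 * np.nansum(total_len[k:]) / (n_animals * genome_length_mbp))
    return np.asarray(out)
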