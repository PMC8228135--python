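"""Reading, writing, merging and quality-filtering PLINK genotype files.

Supports the two PLINK 1.x on-disk layouts: text PED/MAP and binary
BED/BIM/FAM (variant-major, magic bytes ``0x6c 0x1b 0x01``).  Dosages
count the A1 allele.  For PED/MAP, which carries no allele columns, A1 is
assigned deterministically as the lexically smaller observed allele
(configurable to PLINK's minor-allele rule via ``a1_policy="minor"``).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DOG_AUTOSOMES,
    MISSING,
    GenotypeDataset,
    QCReport,
    _chrom_sort_key,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes (variant-major): 00 hom A1, 10 het, 11 hom A2, 01 missing
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


class PlinkFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_plink(
    path_prefix: str | Path,
    dialect: str | None = None,
    a1_policy: str = "alpha",
    autosomes: tuple[str, ...] | None = DOG_AUTOSOMES,
) -> GenotypeDataset:
    """Read a PLINK fileset into a :class:`GenotypeDataset`.

    Parameters
    ----------
    path_prefix
        Path without extension; ``prefix.ped/.map`` or ``prefix.bed/.bim/.fam``.
    dialect
        ``"ped_map"`` or ``"bed_bim_fam"``; autodetected from the files
        present when omitted.
    a1_policy
        How to orient alleles when reading PED/MAP: ``"alpha"`` counts the
        lexically smaller allele, ``"minor"`` the rarer one (ties lexical).
        BIM files carry A1/A2 explicitly and ignore this.
    autosomes
        Chromosome labels to retain (``None`` keeps everything).

    Markers are returned sorted by (chromosome, position).
    """
    prefix = Path(path_prefix)
    if dialect is None:
        if prefix.with_suffix(".bed").exists():
            dialect = "bed_bim_fam"
        elif prefix.with_suffix(".ped").exists():
            dialect = "ped_map"
        else:
            raise FileNotFoundError(f"no .ped or .bed file with prefix {prefix}")
    if dialect == "ped_map":
        ds = _read_ped_map(prefix, a1_policy)
    elif dialect == "bed_bim_fam":
        ds = _read_bed_bim_fam(prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if autosomes is not None:
        keep = ds.markers["chromosome"].isin(autosomes).to_numpy()
        ds = ds.subset_markers(keep)
    return ds.sorted_by_position()


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PlinkFormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], int(parts[3])))
    return pd.DataFrame(rows, columns=["chromosome", "marker_id", "position"])


def _read_ped_map(prefix: Path, a1_policy: str) -> GenotypeDataset:
    markers = _read_map(prefix.with_suffix(".map"))
    m = len(markers)
    sample_rows = []
    allele_pairs = []  # list of (M,) arrays of allele strings, per sample, 2 per marker
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{prefix}.ped:{lineno}: expected {6 + 2 * m} fields for "
                    f"{m} markers, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            sample_rows.append((iid, fid))
            allele_pairs.append(np.array(parts[6:], dtype=object).reshape(m, 2))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "group"])
    if not allele_pairs:
        raise PlinkFormatError(f"{prefix}.ped is empty")
    alleles = np.stack(allele_pairs)  # n x m x 2
    geno = np.full((len(samples), m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise PlinkFormatError(
                f"{prefix}.ped: marker {markers['marker_id'][j]} has "
                f"{len(uniq)} alleles {sorted(uniq)}; only biallelic markers supported"
            )
        if len(uniq) == 0:
            a1, a2 = "0", "0"
        elif len(uniq) == 1:
            a1, a2 = uniq[0], "0"
        elif a1_policy == "minor":
            order = np.lexsort((uniq, counts))  # rarer first, lexical tie-break
            a1, a2 = uniq[order[0]], uniq[order[1]]
        else:  # alpha
            a1, a2 = sorted(uniq)
        a1_list.append(a1)
        a2_list.append(a2)
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        geno[called, j] = (col[called] == a1).sum(axis=1)
    markers = markers.assign(a1=a1_list, a2=a2_list)
    return GenotypeDataset(samples, markers[["marker_id", "chromosome", "position", "a1", "a2"]], geno)


def _read_bed_bim_fam(prefix: Path) -> GenotypeDataset:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str, "marker_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "sample_id": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (not variant-major PLINK bed)")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_variant:
        raise PlinkFormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {m * bytes_per_variant} "
            f"for {n} samples x {m} variants"
        )
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    geno = _BED_CODE_TO_DOSAGE[codes[:, :n]].T  # n x m
    samples = pd.DataFrame({"sample_id": fam["sample_id"], "group": fam["fid"]})
    markers = bim[["marker_id", "chromosome", "position", "a1", "a2"]].copy()
    return GenotypeDataset(samples, markers, np.ascontiguousarray(geno))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_plink(ds: GenotypeDataset, path_prefix: str | Path, dialect: str = "ped_map") -> None:
    """Write a dataset as PED/MAP or BED/BIM/FAM (variant-major)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "ped_map":
        _write_ped_map(ds, prefix)
    elif dialect == "bed_bim_fam":
        _write_bed_bim_fam(ds, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_ped_map(ds: GenotypeDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in ds.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position}\n")
    a1 = ds.markers["a1"].to_numpy()
    a2 = ds.markers["a2"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, srow in enumerate(ds.samples.itertuples(index=False)):
            fields = [str(srow.group), str(srow.sample_id), "0", "0", "0", "-9"]
            g = ds.genotypes[i]
            for j in range(ds.n_markers):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 2:
                    fields += [a1[j], a1[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def _write_bed_bim_fam(ds: GenotypeDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in ds.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position}\t{row.a1}\t{row.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for row in ds.samples.itertuples(index=False):
            fh.write(f"{row.group} {row.sample_id} 0 0 0 -9\n")
    n, m = ds.n_samples, ds.n_markers
    bytes_per_variant = (n + 3) // 4
    code = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    code[:] = 0b01  # pad positions read back as missing but are ignored
    gt = ds.genotypes.T  # m x n
    for dosage, c in _DOSAGE_TO_BED_CODE.items():
        code[:, :n][gt == dosage] = c
    packed = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for shift in range(4):
        packed |= code[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# merging and filtering
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def intersect_and_merge(datasets: list[GenotypeDataset]) -> tuple[GenotypeDataset, QCReport]:
    """Merge datasets on the intersection of their marker ids.

    Alleles are harmonized to the first dataset: a marker whose A1/A2 are
    swapped in a later dataset has its dosages complemented (d -> 2 - d);
    markers with irreconcilable or strand-ambiguous (A/T, C/G) allele
    pairs are dropped and counted in the report.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to merge")
    ref = datasets[0]
    common = set(ref.markers["marker_id"])
    for ds in datasets[1:]:
        common &= set(ds.markers["marker_id"])
    if not common:
        raise ValueError("marker intersection is empty")
    # reference order restricted to common markers
    ref_idx = ref.markers.index[ref.markers["marker_id"].isin(common)].to_numpy()
    ref_markers = ref.markers.loc[ref_idx].reset_index(drop=True)
    keep = np.ones(len(ref_markers), dtype=bool)
    n_conflict = 0
    blocks = [ref.genotypes[:, ref_idx]]
    for ds in datasets[1:]:
        lookup = {mid: k for k, mid in enumerate(ds.markers["marker_id"])}
        cols = np.array([lookup[mid] for mid in ref_markers["marker_id"]])
        sub = ds.genotypes[:, cols].copy()
        a1 = ds.markers["a1"].to_numpy()[cols]
        a2 = ds.markers["a2"].to_numpy()[cols]
        r1 = ref_markers["a1"].to_numpy()
        r2 = ref_markers["a2"].to_numpy()
        same = (a1 == r1) & (a2 == r2)
        swapped = (a1 == r2) & (a2 == r1)
        miss = sub == MISSING
        flip = swapped & ~same
        sub[:, flip] = 2 - sub[:, flip]
        sub[miss] = MISSING
        bad = ~(same | swapped)
        ambiguous = np.array([_is_strand_ambiguous(x, y) for x, y in zip(r1, r2)])
        drop = bad | (ambiguous & ~same)
        n_conflict += int((drop & keep).sum())
        keep &= ~drop
        blocks.append(sub)
    samples = pd.concat([ds.samples for ds in datasets], ignore_index=True)
    geno = np.concatenate(blocks, axis=0)[:, keep]
    merged = GenotypeDataset(samples, ref_markers.loc[keep], geno).sorted_by_position()
    report = QCReport(
        n_markers_in=len(ref_markers),
        n_markers_out=merged.n_markers,
        n_samples_in=merged.n_samples,
        n_samples_out=merged.n_samples,
        thresholds={},
        removed={"allele_conflict_or_ambiguous": n_conflict},
    )
    return merged, report


def filter_missingness(
    ds: GenotypeDataset,
    max_sample_missing: float = 0.10,
    max_marker_missing: float = 0.10,
    order: str = "samples_first",
) -> tuple[GenotypeDataset, QCReport]:
    """Remove samples then markers whose missing fraction exceeds a threshold.

    Follows PLINK ``--mind`` / ``--geno`` semantics: strictly greater than
    the threshold removes, equality retains.  Default order removes samples
    first (then recomputes marker missingness on the surviving samples).
    """
    for t in (max_sample_missing, max_marker_missing):
        if not 0 <= t <= 1:
            raise ValueError("missingness thresholds must lie in [0, 1]")

    def drop_samples(d: GenotypeDataset) -> tuple[GenotypeDataset, int]:
        frac = d.missing_mask().mean(axis=1)
        keep = frac <= max_sample_missing
        return d.subset_samples(keep), int((~keep).sum())

    def drop_markers(d: GenotypeDataset) -> tuple[GenotypeDataset, int]:
        frac = d.missing_mask().mean(axis=0)
        keep = frac <= max_marker_missing
        return d.subset_markers(keep), int((~keep).sum())

    if order == "samples_first":
        out, ns = drop_samples(ds)
        out, nm = drop_markers(out)
    elif order == "markers_first":
        out, nm = drop_markers(ds)
        out, ns = drop_samples(out)
    else:
        raise ValueError(f"unknown order {order!r}")
    if out.n_samples == 0:
        raise ValueError("all samples removed by missingness filter")
    if out.n_markers == 0:
        raise ValueError("all markers removed by missingness filter")
    report = QCReport(
        n_markers_in=ds.n_markers,
        n_markers_out=out.n_markers,
        n_samples_in=ds.n_samples,
        n_samples_out=out.n_samples,
        thresholds={
            "max_sample_missing": max_sample_missing,
            "max_marker_missing": max_marker_missing,
            "order": order,
        },
        removed={"samples_missingness": ns, "markers_missingness": nm},
    )
    return out, report


def genome_span(ds: GenotypeDataset) -> tuple[int, pd.DataFrame]:
    """SNP-covered genome length: per-chromosome max - min position, summed.

    Returns the total span in bp and a per-chromosome table.  Chromosomes
    with fewer than two markers contribute 0 bp (with a warning).
    """
    rows = []
    for chrom, grp in ds.markers.groupby("chromosome", sort=False):
        if len(grp) < 2:
            warnings.warn(f"chromosome {chrom} has <2 markers; span set to 0")
            span = 0
        else:
            span = int(grp["position"].max() - grp["position"].min())
        rows.append((chrom, len(grp), span))
    per_chrom = pd.DataFrame(rows, columns=["chromosome", "n_markers", "span_bp"])
    per_chrom = per_chrom.sort_values(
        "chromosome", key=_chrom_sort_key, kind="mergesort"
    ).reset_index(drop=True)
    return int(per_chrom["span_bp"].sum()), per_chrom
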