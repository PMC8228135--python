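"""Synthetic genotype data with known truth for every pipeline stage.

Divergent populations follow the Balding-Nichols model: an ancestral
frequency p ~ U(0.05, 0.95) per locus, a per-population frequency drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) at divergence F, and genotypes from
Binomial(2, freq).  Admixed samples draw each allele copy from a mixture
q f_A + (1-q) f_B with a recorded true ancestry fraction q.  Autozygous
tracts with exponential lengths can be implanted to a target F_ROH, and
genotypes can be masked at random to emulate missingness.  Everything is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset


@dataclass
class SimConfig:
    """Study-condition knobs for the Balding-Nichols generator.

    Defaults give a dog-like but desk-scale geometry: 10 chromosomes of
    60 Mbp at roughly one SNP per 60 kb (10,000 loci), five populations of
    25 samples at F = 0.2 — the sampling depth and divergence regime of a
    five-breed SNP-array panel, scaled to seconds of compute.
    """

    n_populations: int = 5
    fst: float | tuple = 0.2
    n_loci: int = 10_000
    n_per_population: int | tuple = 25
    ancestral_range: tuple = (0.05, 0.95)
    n_chromosomes: int = 10
    chromosome_length_bp: int = 60_000_000
    missing_rate: float = 0.0
    seed: int = 0
    population_names: tuple | None = None

    def __post_init__(self) -> None:
        fsts = self.fst if isinstance(self.fst, (tuple, list)) else (self.fst,)
        if any(not 0 <= f < 1 for f in fsts):
            raise ValueError("F must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class TruthSet:
    """What the generator actually did, for recovery scoring."""

    labels: np.ndarray | None = None            # per-sample population label
    Q: np.ndarray | None = None                 # per-sample true ancestry fractions
    population_freqs: np.ndarray | None = None  # pops x loci
    ancestral_freqs: np.ndarray | None = None
    tracts: pd.DataFrame | None = None          # sample_id, chromosome, start_bp, end_bp
    realized_froh: pd.Series | None = None      # per sample


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    rows = []
    for c in range(config.n_chromosomes):
        want = per_chrom[c]
        pos = np.unique(rng.integers(1, config.chromosome_length_bp, size=2 * want + 16))
        while pos.size < want:  # collisions are rare at realistic densities
            extra = rng.integers(1, config.chromosome_length_bp, size=2 * want)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        for p in pos:
            rows.append((f"snp_{c + 1}_{p}", str(c + 1), int(p), "A", "G"))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "a1", "a2"])


def simulate_balding_nichols(config: SimConfig) -> tuple[GenotypeDataset, TruthSet]:
    """K divergent populations with controlled F_ST under Balding-Nichols."""
    rng = np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    m = len(markers)
    k = config.n_populations
    names = (
        list(config.population_names)
        if config.population_names is not None
        else [f"POP{i + 1}" for i in range(k)]
    )
    sizes = (
        list(config.n_per_population)
        if isinstance(config.n_per_population, (tuple, list))
        else [config.n_per_population] * k
    )
    fsts = (
        list(config.fst) if isinstance(config.fst, (tuple, list)) else [config.fst] * k
    )
    lo, hi = config.ancestral_range
    anc = rng.uniform(lo, hi, size=m)
    pop_freqs = np.empty((k, m))
    for i in range(k):
        f = fsts[i]
        if f == 0:
            pop_freqs[i] = anc
        else:
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            pop_freqs[i] = rng.beta(a, b)
    rows, geno_blocks, labels = [], [], []
    for i in range(k):
        geno_blocks.append(rng.binomial(2, pop_freqs[i], size=(sizes[i], m)).astype(np.int8))
        rows += [(f"{names[i]}_{s + 1:03d}", names[i]) for s in range(sizes[i])]
        labels += [names[i]] * sizes[i]
    samples = pd.DataFrame(rows, columns=["sample_id", "group"])
    ds = GenotypeDataset(samples, markers, np.concatenate(geno_blocks, axis=0))
    labels = np.asarray(labels, dtype=object)
    Q = np.zeros((len(labels), k))
    for i, nm in enumerate(names):
        Q[labels == nm, i] = 1.0
    truth = TruthSet(labels=labels, Q=Q, population_freqs=pop_freqs, ancestral_freqs=anc)
    if config.missing_rate > 0:
        ds = add_missingness(ds, config.missing_rate, int(rng.integers(2**31)))
    return ds, truth


def simulate_admixed(
    pop_a_freqs: np.ndarray,
    pop_b_freqs: np.ndarray,
    q_values,
    markers: pd.DataFrame,
    seed: int,
    group: str = "ADMIXED",
    id_prefix: str = "ADM",
) -> tuple[GenotypeDataset, TruthSet]:
    """Admixed samples with known ancestry fraction q towards population A.

    Each allele copy comes from A with probability q, so the genotype is
    Binomial(2, q f_A + (1-q) f_B) per locus.
    """
    pop_a_freqs = np.asarray(pop_a_freqs, dtype=float)
    pop_b_freqs = np.asarray(pop_b_freqs, dtype=float)
    if pop_a_freqs.shape != pop_b_freqs.shape:
        raise ValueError("frequency vectors have unequal length")
    q_values = np.asarray(q_values, dtype=float)
    if np.any((q_values < 0) | (q_values > 1)):
        raise ValueError("q values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mix = q_values[:, None] * pop_a_freqs[None, :] + (1 - q_values[:, None]) * pop_b_freqs[None, :]
    geno = rng.binomial(2, mix).astype(np.int8)
    samples = pd.DataFrame(
        {
            "sample_id": [f"{id_prefix}_{i + 1:03d}" for i in range(len(q_values))],
            "group": group,
        }
    )
    ds = GenotypeDataset(samples, markers.reset_index(drop=True), geno)
    Q = np.column_stack([q_values, 1 - q_values])
    return ds, TruthSet(labels=np.array([group] * len(q_values), dtype=object), Q=Q)


def implant_roh(
    ds: GenotypeDataset,
    target_froh: float,
    mean_tract_mbp: float = 8.0,
    min_tract_mbp: float = 1.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[GenotypeDataset, TruthSet]:
    """Overwrite genotypes inside random non-overlapping autozygous tracts.

    Tracts have exponential lengths (mean ``mean_tract_mbp``, truncated
    below at ``min_tract_mbp``), are placed uniformly on chromosomes
    chosen proportionally to length, and accumulate per sample until the
    realized F_ROH (tract bp / SNP-covered genome bp) reaches the target.
    Inside a tract every SNP becomes homozygous, the allele drawn once per
    locus with the dataset-wide A1 frequency.  Placement rejects overlaps;
    exceeding ``max_attempts`` raises.
    """
    from .genotype_io import genome_span

    if target_froh == 0:
        return ds.copy(), TruthSet(
            tracts=pd.DataFrame(columns=["sample_id", "chromosome", "start_bp", "end_bp"]),
            realized_froh=pd.Series(0.0, index=ds.samples["sample_id"]),
        )
    total_bp, per_chrom = genome_span(ds)
    if not 0 < target_froh < 1:
        raise ValueError("target_froh must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    called = ds.genotypes != MISSING
    n_alleles = 2 * called.sum(axis=0)
    freq = np.divide(
        np.where(called, ds.genotypes, 0).sum(axis=0),
        np.maximum(n_alleles, 1),
        out=np.full(ds.n_markers, 0.5),
        where=n_alleles > 0,
    )
    chroms = per_chrom["chromosome"].to_numpy()
    spans = per_chrom["span_bp"].to_numpy(dtype=float)
    starts = {
        c: int(ds.markers.loc[ds.markers["chromosome"] == c, "position"].min()) for c in chroms
    }
    weights = spans / spans.sum()
    marker_chrom = ds.markers["chromosome"].to_numpy()
    marker_pos = ds.markers["position"].to_numpy()
    tract_rows = []
    froh_vals = []
    for i, sid in enumerate(ds.samples["sample_id"]):
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        covered = 0
        attempts = 0
        while covered < target_froh * total_bp:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place tracts for {sid} without overlap after {max_attempts} tries"
                )
            c = rng.choice(chroms, p=weights)
            length = max(rng.exponential(mean_tract_mbp), min_tract_mbp) * 1_000_000
            # truncate the last tract towards the remaining requirement so the
            # realized F_ROH lands just above the target
            need = target_froh * total_bp - covered
            if length > need:
                length = max(need, min_tract_mbp * 1_000_000)
            span = spans[list(chroms).index(c)]
            if length >= span:
                continue
            s = starts[c] + int(rng.uniform(0, span - length))
            e = s + int(length) - 1
            if any(not (e < a or s > b) for a, b in placed[c]):
                continue
            placed[c].append((s, e))
            covered += e - s + 1
            inside = (marker_chrom == c) & (marker_pos >= s) & (marker_pos <= e)
            idx = np.flatnonzero(inside)
            allele = rng.random(idx.size) < freq[idx]
            out.genotypes[i, idx] = np.where(allele, 2, 0).astype(np.int8)
            tract_rows.append((sid, c, s, e))
        froh_vals.append(covered / total_bp)
    tracts = pd.DataFrame(tract_rows, columns=["sample_id", "chromosome", "start_bp", "end_bp"])
    truth = TruthSet(
        tracts=tracts,
        realized_froh=pd.Series(froh_vals, index=ds.samples["sample_id"].tolist()),
    )
    return out, truth


def add_missingness(ds: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Mask each genotype independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return ds.copy()
    rng = np.random.default_rng(seed)
    out = ds.copy()
    mask = rng.random(out.genotypes.shape) < rate
    out.genotypes[mask] = MISSING
    return out


def five_breeds_preset(
    seed: int = 0,
    n_loci: int = 8000,
    scale: float = 1.0,
) -> tuple[GenotypeDataset, TruthSet]:
    """Five-group panel emulating the empirical study design.

    Four diverged source groups (BSD, GSD, GW, SWD) plus a hybrid CWD
    cohort formed by GSD x GW admixture (q towards GSD around 0.75,
    matching a dog breed founded from shepherd-dog x wolf crosses and
    back-crossed towards the dog), with implanted autozygous tracts in the
    domesticated groups.  ``scale`` multiplies group sizes.
    """
    rng = np.random.default_rng(seed)
    sizes = {"BSD": 31, "GSD": 56, "GW": 30, "SWD": 6}
    sizes = {k: max(4, int(round(v * scale))) for k, v in sizes.items()}
    n_cwd = max(4, int(round(30 * scale)))
    config = SimConfig(
        n_populations=4,
        fst=0.2,
        n_loci=n_loci,
        n_per_population=tuple(sizes.values()),
        population_names=tuple(sizes.keys()),
        n_chromosomes=10,
        chromosome_length_bp=60_000_000,
        seed=int(rng.integers(2**31)),
    )
    base, truth = simulate_balding_nichols(config)
    gsd = list(config.population_names).index("GSD")
    gw = list(config.population_names).index("GW")
    q = np.clip(rng.normal(0.75, 0.05, size=n_cwd), 0.55, 0.95)
    cwd, cwd_truth = simulate_admixed(
        truth.population_freqs[gsd],
        truth.population_freqs[gw],
        q,
        base.markers,
        seed=int(rng.integers(2**31)),
        group="CWD",
        id_prefix="CWD",
    )
    samples = pd.concat([base.samples, cwd.samples], ignore_index=True)
    geno = np.concatenate([base.genotypes, cwd.genotypes], axis=0)
    ds = GenotypeDataset(samples, base.markers, geno)
    # recent inbreeding: strongest in the hybrid breed, absent in wolves
    targets = {"CWD": 0.10, "GSD": 0.06, "BSD": 0.05, "SWD": 0.08, "GW": 0.0}
    tract_frames, froh_parts = [], []
    for grp, tgt in targets.items():
        idx = np.flatnonzero(ds.samples["group"].to_numpy() == grp)
        sub = ds.subset_samples(idx)
        if tgt > 0:
            sub, t = implant_roh(sub, tgt, mean_tract_mbp=8.0, seed=int(rng.integers(2**31)))
            tract_frames.append(t.tracts)
            froh_parts.append(t.realized_froh)
            ds.genotypes[idx] = sub.genotypes
        else:
            froh_parts.append(pd.Series(0.0, index=sub.samples["sample_id"].tolist()))
    labels = ds.samples["group"].to_numpy(dtype=object)
    k_names = ["BSD", "GSD", "GW", "SWD", "CWD"]
    Q = np.zeros((ds.n_samples, 5))
    for j, nm in enumerate(k_names[:4]):
        Q[labels == nm, j] = 1.0
    is_cwd = labels == "CWD"
    Q[is_cwd, k_names.index("GSD")] = cwd_truth.Q[:, 0]
    Q[is_cwd, k_names.index("GW")] = cwd_truth.Q[:, 1]
    truth_all = TruthSet(
        labels=labels,
        Q=Q,
        population_freqs=truth.population_freqs,
        ancestral_freqs=truth.ancestral_freqs,
        tracts=pd.concat(tract_frames, ignore_index=True) if tract_frames else None,
        realized_froh=pd.concat(froh_parts),
    )
    return ds, truth_all
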