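import numpy as np
import pandas as pd
import pytest

from canid.datatypes import GenotypeDataset
from canid.simulate import SimConfig, simulate_balding_nichols


def make_dataset(genotypes, positions=None, chromosome="1", groups=None, a1="A", a2="G"):
    """Small hand-built dataset helper used across the suite."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if positions is None:
        positions = [100_000 * (j + 1) for j in range(m)]
    if isinstance(chromosome, str):
        chroms = [chromosome] * m
    else:
        chroms = list(chromosome)
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{j}" for j in range(m)],
            "chromosome": chroms,
            "position": positions,
            "a1": a1,
            "a2": a2,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group": groups if groups is not None else ["g1"] * n,
        }
    )
    return GenotypeDataset(samples, markers, genotypes)


@pytest.fixture
def tiny_ds():
    """2 samples x 3 markers, no missing data."""
    return make_dataset([[0, 1, 2], [2, 1, 0]])


@pytest.fixture(scope="session")
def two_pop_ds():
    """Two Balding-Nichols populations at F = 0.2, 30 + 30 samples, 2000 loci."""
    cfg = SimConfig(
        n_populations=2, fst=0.2, n_loci=2000, n_per_population=30,
        n_chromosomes=4, seed=101,
    )
    return simulate_balding_nichols(cfg)


@pytest.fixture(scope="session")
def five_pop_ds():
    """Five populations at F = 0.2, 20 per group, 2000 loci."""
    cfg = SimConfig(
        n_populations=5, fst=0.2, n_loci=2000, n_per_population=20,
        n_chromosomes=4, seed=202,
    )
    return simulate_balding_nichols(cfg)
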