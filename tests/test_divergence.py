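import math

import numpy as np
import pytest

from canid import divergence
from canid.datatypes import MISSING
from canid.reference_tables import published_fst_matrix, published_nei_matrix
from canid.simulate import SimConfig, simulate_balding_nichols

from conftest import make_dataset


def wc_theta_literal(samples_by_pop):
    """Independent oracle: Weir & Cockerham (1984) theta, transcribed
    term by term from the two-population biallelic variance-component
    formulas, evaluated with plain Python loops per locus."""
    r = len(samples_by_pop)
    n_loci = len(samples_by_pop[0][0])
    sum_a = sum_abc = 0.0
    for locus in range(n_loci):
        ns, ps, hs = [], [], []
        for pop in samples_by_pop:
            calls = [g[locus] for g in pop if g[locus] != MISSING]
            if not calls:
                break
            ns.append(len(calls))
            ps.append(sum(calls) / (2 * len(calls)))
            hs.append(sum(1 for c in calls if c == 1) / len(calls))
        else:
            if sum(ns) <= 2:
                continue
            nbar = sum(ns) / r
            total = sum(ns)
            nc = (total - sum(n * n for n in ns) / total) / (r - 1)
            pbar = sum(n * p for n, p in zip(ns, ps)) / total
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / total
            pq = pbar * (1 - pbar)
            a = (nbar / nc) * (
                s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc else math.nan


class TestAlleleFreqs:
    def test_three_genotypes_give_half(self):
        ds = make_dataset([[0], [1], [2]])
        table = divergence.allele_freqs(ds)
        assert table.freqs[0, 0] == pytest.approx(0.5)
        assert table.counts[0, 0] == 6

    def test_all_missing_marker_flagged(self):
        ds = make_dataset([[MISSING, 1], [MISSING, 1]])
        table = divergence.allele_freqs(ds)
        assert np.isnan(table.freqs[0, 0])
        assert table.freqs[0, 1] == pytest.approx(0.5)

    def test_matches_bruteforce_counting(self):
        rng = np.random.default_rng(5)
        g = rng.choice([0, 1, 2, MISSING], size=(20, 50), p=[0.3, 0.3, 0.3, 0.1])
        groups = ["A"] * 10 + ["B"] * 10
        ds = make_dataset(g, groups=groups)
        table = divergence.allele_freqs(ds)
        for gi, grp in enumerate(table.groups):
            rows = [i for i, x in enumerate(groups) if x == grp]
            for j in range(50):
                calls = [g[i, j] for i in rows if g[i, j] != MISSING]
                if calls:
                    assert table.freqs[gi, j] == pytest.approx(sum(calls) / (2 * len(calls)))
                else:
                    assert np.isnan(table.freqs[gi, j])

    def test_individual_level_frequencies(self):
        ds = make_dataset([[0, 1, 2]])
        table = divergence.allele_freqs(ds, by=None)
        assert table.freqs[0].tolist() == [0.0, 0.5, 1.0]


class TestNei:
    def test_identical_vectors_zero_distance(self):
        freqs = divergence.AlleleFreqTable(
            ["x", "y"], ["m1", "m2"], np.array([[0.3, 0.7], [0.3, 0.7]]), np.ones((2, 2))
        )
        for method in ("nei1972", "nei1983"):
            assert divergence.nei_distance(freqs, method).values[0, 1] == pytest.approx(0.0)

    def test_single_locus_hand_value(self):
        freqs = divergence.AlleleFreqTable(
            ["x", "y"], ["m1"], np.array([[0.8], [0.2]]), np.ones((2, 1))
        )
        d = divergence.nei_distance(freqs, "nei1972").values[0, 1]
        assert d == pytest.approx(-math.log(0.32 / 0.68), abs=1e-6)

    def test_opposite_fixation_flagged_infinite(self):
        freqs = divergence.AlleleFreqTable(
            ["x", "y"], ["m1"], np.array([[1.0], [0.0]]), np.ones((2, 1))
        )
        assert divergence.nei_distance(freqs, "nei1972").values[0, 1] == divergence.NEI_INF

    def test_ranges_and_symmetry(self, five_pop_ds):
        ds, _ = five_pop_ds
        freqs = divergence.allele_freqs(ds)
        d72 = divergence.nei_distance(freqs, "nei1972")
        d83 = divergence.nei_distance(freqs, "nei1983")
        for dm in (d72, d83):
            assert np.allclose(dm.values, dm.values.T)
            assert np.allclose(np.diag(dm.values), 0)
        assert (d72.values >= 0).all()
        assert ((d83.values >= 0) & (d83.values <= 1)).all()


class TestWcFst:
    def test_identical_generating_frequencies_near_zero(self, two_pop_ds):
        # split one population in half: no true differentiation
        ds, truth = two_pop_ds
        half = ds.subset_samples(np.arange(30))
        labels = ["L"] * 15 + ["R"] * 15
        half.samples = half.samples.assign(group=labels)
        dm = divergence.wc_fst_pairwise(half)
        assert abs(dm.extras["raw"][0, 1]) < 0.01

    def test_fixed_difference_gives_one(self):
        g = np.vstack([np.full((5, 30), 2), np.full((5, 30), 0)]).astype(np.int8)
        ds = make_dataset(g, groups=["A"] * 5 + ["B"] * 5)
        dm = divergence.wc_fst_pairwise(ds)
        assert dm.pair("A", "B") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_literal_transcription(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.choice([0, 1, 2, MISSING], size=(10, 12), p=[0.3, 0.3, 0.3, 0.1])
        ds = make_dataset(g, groups=["A"] * 5 + ["B"] * 5)
        dm = divergence.wc_fst_pairwise(ds)
        expected = wc_theta_literal([list(g[:5]), list(g[5:])])
        assert dm.extras["raw"][0, 1] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_allele_label_swap(self, two_pop_ds):
        ds, _ = two_pop_ds
        flipped = ds.copy()
        cols = np.arange(0, ds.n_markers, 3)
        sub = flipped.genotypes[:, cols]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        flipped.genotypes[:, cols] = sub
        d0 = divergence.wc_fst_pairwise(ds)
        d1 = divergence.wc_fst_pairwise(flipped)
        assert d0.pair("POP1", "POP2") == pytest.approx(d1.pair("POP1", "POP2"), abs=1e-12)

    @pytest.mark.parametrize("F", [0.05, 0.1, 0.2])
    def test_balding_nichols_expectation(self, F):
        """Mean theta across replicates tracks the Monte-Carlo expectation
        for two populations independently drawn at divergence F."""
        n_per, n_loci = 40, 3000
        measured = []
        for seed in (1, 2, 3):
            cfg = SimConfig(n_populations=2, fst=F, n_loci=n_loci,
                            n_per_population=n_per, n_chromosomes=2, seed=seed)
            ds, _ = simulate_balding_nichols(cfg)
            measured.append(divergence.wc_fst_pairwise(ds).extras["raw"][0, 1])
        # Monte-Carlo expectation: fresh frequency draws, HWE genotype
        # sampling at the same depth, literal component formulas
        rng = np.random.default_rng(12345)
        n_mc = 50_000
        anc = rng.uniform(0.05, 0.95, size=n_mc)
        p_pops = [
            rng.beta(anc * (1 - F) / F, (1 - anc) * (1 - F) / F) for _ in range(2)
        ]
        phat, hobs = [], []
        for p in p_pops:
            hwe = np.stack([p**2, 2 * p * (1 - p), (1 - p) ** 2], axis=1)
            counts = np.array([rng.multinomial(n_per, w) for w in hwe])
            phat.append((2 * counts[:, 0] + counts[:, 1]) / (2 * n_per))
            hobs.append(counts[:, 1] / n_per)
        x, y = phat
        hx, hy = hobs
        nbar = nc = n_per
        pbar = (x + y) / 2
        s2 = (x - y) ** 2 / 2
        hbar = (hx + hy) / 2
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (s2 - (pq - s2 / 2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pq - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        expected = a.sum() / (a + b + c).sum()
        assert np.mean(measured) == pytest.approx(expected, rel=0.15)


class TestSummaries:
    def test_published_wolf_row_nei_summary(self):
        mean, sd = divergence.summarize_vs_group(published_nei_matrix(), "GW")
        assert round(mean, 2) == 0.20
        assert round(sd, 2) == 0.02

    def test_published_wolf_column_fst_summary(self):
        mean, sd = divergence.summarize_vs_group(published_fst_matrix(), "GW")
        assert round(mean, 2) == 0.33
        assert round(sd, 2) == 0.03

    def test_constant_row_zero_sd(self):
        from canid.datatypes import DistanceMatrix

        m = np.array([[0, 0.2, 0.2], [0.2, 0, 0.5], [0.2, 0.5, 0]])
        mean, sd = divergence.summarize_vs_group(DistanceMatrix(["a", "b", "c"], m, "ibs"), "a")
        assert (mean, sd) == (pytest.approx(0.2), pytest.approx(0.0))

    def test_combined_table_layout(self):
        fst, nei = published_fst_matrix(), published_nei_matrix()
        table = divergence.combined_table(fst, nei)
        assert table.loc["GW", "CWD"] == 0.319   # F_ST below the diagonal
        assert table.loc["CWD", "GW"] == 0.169   # Nei above
        assert np.isnan(table.loc["CWD", "CWD"])
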