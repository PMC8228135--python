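import numpy as np
import pandas as pd
import pytest

from canid.datatypes import MISSING, GenotypeDataset
from canid.genotype_io import (
    filter_missingness,
    genome_span,
    intersect_and_merge,
    read_plink,
    write_plink,
)
from canid.simulate import SimConfig, add_missingness, simulate_balding_nichols

from conftest import make_dataset


@pytest.fixture
def ped_fixture(tmp_path, tiny_ds):
    write_plink(tiny_ds, tmp_path / "toy", "ped_map")
    return tmp_path / "toy"


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["ped_map", "bed_bim_fam"])
    def test_write_read_identity(self, tmp_path, dialect):
        cfg = SimConfig(n_populations=2, fst=0.1, n_loci=120, n_per_population=5,
                        n_chromosomes=3, seed=7, missing_rate=0.05)
        ds, _ = simulate_balding_nichols(cfg)
        if dialect == "ped_map":
            # PED carries no allele columns, so an allele absent from the
            # data cannot survive the trip: keep polymorphic markers only
            g = ds.genotypes
            poly = (g > 0).any(axis=0) & ((g >= 0) & (g < 2)).any(axis=0)
            ds = ds.subset_markers(poly)
        write_plink(ds, tmp_path / "rt", dialect)
        back = read_plink(tmp_path / "rt", dialect)
        assert back.equals(ds.sorted_by_position())

    def test_cross_dialect_equality(self, tmp_path, tiny_ds):
        write_plink(tiny_ds, tmp_path / "a", "ped_map")
        write_plink(tiny_ds, tmp_path / "b", "bed_bim_fam")
        from_ped = read_plink(tmp_path / "a", "ped_map")
        from_bed = read_plink(tmp_path / "b", "bed_bim_fam")
        assert from_ped.equals(from_bed)

    def test_ped_00_is_missing(self, tmp_path):
        (tmp_path / "m.map").write_text("1\tsnp0\t0\t1000\n")
        (tmp_path / "m.ped").write_text("f1 s1 0 0 0 -9 0 0\nf1 s2 0 0 0 -9 A G\n")
        ds = read_plink(tmp_path / "m", "ped_map")
        assert ds.genotypes[0, 0] == MISSING
        assert ds.genotypes[1, 0] == 1

    def test_malformed_ped_line_reports_line_number(self, tmp_path):
        (tmp_path / "m.map").write_text("1\tsnp0\t0\t1000\n")
        (tmp_path / "m.ped").write_text("f1 s1 0 0 0 -9 A\n")
        with pytest.raises(ValueError, match="m.ped:1"):
            read_plink(tmp_path / "m", "ped_map")

    def test_non_biallelic_marker_rejected(self, tmp_path):
        (tmp_path / "m.map").write_text("1\tsnp0\t0\t1000\n")
        (tmp_path / "m.ped").write_text(
            "f1 s1 0 0 0 -9 A G\nf1 s2 0 0 0 -9 C C\n"
        )
        with pytest.raises(ValueError, match="allele"):
            read_plink(tmp_path / "m", "ped_map")


class TestMerge:
    def test_merge_with_itself_doubles_samples(self, tiny_ds):
        other = tiny_ds.copy()
        other.samples = other.samples.assign(sample_id=["t0", "t1"])
        merged, report = intersect_and_merge([tiny_ds, other])
        assert merged.n_markers == tiny_ds.n_markers
        assert merged.n_samples == 2 * tiny_ds.n_samples
        assert np.array_equal(merged.genotypes[:2], merged.genotypes[2:])

    def test_intersection_of_marker_sets(self):
        a = make_dataset(np.zeros((2, 5), dtype=int))
        b = make_dataset(np.zeros((2, 4), dtype=int))
        b.samples = b.samples.assign(sample_id=["t0", "t1"])
        b.markers = b.markers.assign(marker_id=["snp1", "snp2", "snp3", "snpX"])
        merged, _ = intersect_and_merge([a, b])
        assert sorted(merged.markers["marker_id"]) == ["snp1", "snp2", "snp3"]

    def test_swapped_alleles_complemented(self):
        # same physical genotypes coded against opposite counted alleles
        a = make_dataset([[0], [1], [2]], a1="A", a2="G")
        b = make_dataset([[2], [1], [0]], a1="G", a2="A")
        b.samples = b.samples.assign(sample_id=["t0", "t1", "t2"])
        merged, _ = intersect_and_merge([a, b])
        # after harmonization to a's orientation, b's dosages are 2 - d
        assert merged.genotypes[:, 0].tolist() == [0, 1, 2, 0, 1, 2]

    def test_strand_ambiguous_marker_dropped_and_counted(self):
        a = make_dataset([[0], [1]], a1="A", a2="T")
        b = make_dataset([[0], [1]], a1="T", a2="A")
        b.samples = b.samples.assign(sample_id=["t0", "t1"])
        merged, report = intersect_and_merge([a, b])
        assert merged.n_markers == 0
        assert report.removed["allele_conflict_or_ambiguous"] == 1

    def test_marker_set_commutative(self, tiny_ds):
        other = make_dataset([[1, 1, 1, 1]], a1="A", a2="G")
        other.samples = other.samples.assign(sample_id=["z0"])
        other.markers = other.markers.assign(marker_id=["snp2", "snp1", "snp0", "snpX"],
                                             position=[5000, 6000, 7000, 8000])
        m1, _ = intersect_and_merge([tiny_ds, other])
        m2, _ = intersect_and_merge([other, tiny_ds])
        assert set(m1.markers["marker_id"]) == set(m2.markers["marker_id"])

    def test_empty_intersection_raises(self, tiny_ds):
        other = tiny_ds.copy()
        other.markers = other.markers.assign(marker_id=["x0", "x1", "x2"])
        with pytest.raises(ValueError, match="empty"):
            intersect_and_merge([tiny_ds, other])


class TestMissingnessFilter:
    def test_no_missing_data_unchanged(self, tiny_ds):
        out, report = filter_missingness(tiny_ds, 0.10, 0.10)
        assert out.equals(tiny_ds)
        assert report.n_samples_removed == 0 and report.n_markers_removed == 0

    def test_sample_above_threshold_removed(self):
        # 10 samples x 100 markers; sample 0 has 11 % missing
        g = np.ones((10, 100), dtype=np.int8)
        g[0, :11] = MISSING
        ds = make_dataset(g)
        out, report = filter_missingness(ds, 0.10, 0.50)
        assert out.n_samples == 9
        assert "s0" not in set(out.samples["sample_id"])
        assert report.removed["samples_missingness"] == 1

    def test_equality_retains(self):
        g = np.ones((10, 100), dtype=np.int8)
        g[0, :10] = MISSING  # exactly 10 %
        ds = make_dataset(g)
        out, _ = filter_missingness(ds, 0.10, 0.50)
        assert out.n_samples == 10

    def test_idempotent(self, two_pop_ds):
        ds, _ = two_pop_ds
        noisy = add_missingness(ds, 0.05, seed=3)
        once, _ = filter_missingness(noisy, 0.08, 0.08)
        twice, _ = filter_missingness(once, 0.08, 0.08)
        assert once.equals(twice)

    def test_counts_reconcile(self, two_pop_ds):
        ds, _ = two_pop_ds
        noisy = add_missingness(ds, 0.1, seed=4)
        out, report = filter_missingness(noisy, 0.09, 0.12)
        assert report.n_samples_out + report.n_samples_removed == report.n_samples_in
        assert report.n_markers_out + report.n_markers_removed == report.n_markers_in
        assert report.n_samples_out == out.n_samples
        assert report.n_markers_out == out.n_markers

    def test_all_removed_raises(self):
        g = np.full((3, 5), MISSING, dtype=np.int8)
        g[:, 0] = 1  # keep one column so samples survive partially
        ds = make_dataset(g)
        with pytest.raises(ValueError):
            filter_missingness(ds, 0.0, 0.0)


class TestGenomeSpan:
    def test_single_chromosome(self):
        ds = make_dataset([[0, 0]], positions=[1_000, 1_001_000])
        total, per_chrom = genome_span(ds)
        assert total == 1_000_000

    def test_two_chromosomes_sum(self):
        ds = make_dataset(
            [[0, 0, 0, 0]],
            positions=[1, 5_000_001, 10, 7_000_010],
            chromosome=["1", "1", "2", "2"],
        )
        total, _ = genome_span(ds)
        assert total == 12_000_000

    def test_single_marker_chromosome_warns_zero(self):
        ds = make_dataset([[0, 0, 0]], positions=[5, 10, 7], chromosome=["1", "1", "2"])
        with pytest.warns(UserWarning, match="chromosome 2"):
            total, per_chrom = genome_span(ds)
        assert per_chrom.set_index("chromosome").loc["2", "span_bp"] == 0

    def test_matches_bruteforce_on_38_autosomes(self):
        rng = np.random.default_rng(11)
        chroms, positions = [], []
        for c in range(1, 39):
            pos = np.sort(rng.choice(10_000_000, size=5, replace=False) + 1)
            chroms += [str(c)] * 5
            positions += pos.tolist()
        ds = make_dataset(np.zeros((1, len(positions)), dtype=int), positions=positions,
                          chromosome=chroms)
        total, _ = genome_span(ds)
        expected = sum(
            max(p for p, cc in zip(positions, chroms) if cc == c)
            - min(p for p, cc in zip(positions, chroms) if cc == c)
            for c in set(chroms)
        )
        assert total == expected
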