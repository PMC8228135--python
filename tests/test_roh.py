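import math

import numpy as np
import pytest

from canid import roh
from canid.datatypes import MISSING
from canid.reference_tables import (
    AUTOSOME_LENGTH_MBP,
    ROH_CLASS_SUMMARY,
)

from conftest import make_dataset


def brute_force_roh(genotypes, positions, params, min_snps):
    """Independent oracle: enumerate maximal homozygous runs directly.

    Splits the genotype string at every heterozygote/missing call and at
    every gap larger than max_gap_bp, then filters each maximal run by
    the same length / count / density rules.  Valid only for the
    no-het-allowed setting.
    """
    segments = []
    run = []
    breaks = [False] + [
        positions[j] - positions[j - 1] > params.max_gap_bp for j in range(1, len(positions))
    ]
    for j, g in enumerate(genotypes):
        if g in (1, MISSING) or (breaks[j] and run):
            if run:
                segments.append(run)
            run = [j] if g not in (1, MISSING) else []
        else:
            run.append(j)
    if run:
        segments.append(run)
    out = []
    for run in segments:
        start, end, n = positions[run[0]], positions[run[-1]], len(run)
        length = end - start + 1
        if (
            length >= params.min_length_bp
            and n >= min_snps
            and length / n <= params.min_density_bp_per_snp
        ):
            out.append((start, end, n))
    return out


class TestLenczMinSnps:
    def test_numerator_equals_denominator_gives_one(self):
        alpha, ns, ni = 0.05, 100, 10
        het = 1 - alpha / (ns * ni)
        assert roh.lencz_min_snps(alpha, ns, ni, het) == 1

    def test_panel_scale_evaluation(self):
        # ln(0.05 / (143593 * 131)) / ln(0.75) = 68.6... -> floor 68
        assert roh.lencz_min_snps(0.05, 143_593, 131, 0.25) == 68

    def test_het_near_026_reproduces_the_reported_65(self):
        # invert the formula for l = 65.5 to find the heterozygosity at
        # which the reported minimum of 65 SNPs is the floored value
        target = math.log(0.05 / (143_593 * 131)) / 65.5
        het = 1 - math.exp(target)
        assert 0.25 < het < 0.27
        assert roh.lencz_min_snps(0.05, 143_593, 131, het) == 65

    def test_invalid_heterozygosity_rejected(self):
        with pytest.raises(ValueError):
            roh.lencz_min_snps(0.05, 100, 10, 1.0)


class TestDetect:
    def test_all_heterozygous_yields_nothing(self):
        ds = make_dataset(np.ones((2, 20), dtype=int))
        seg = roh.detect_roh(ds, roh.ROHParams(min_snps=2))
        assert len(seg) == 0

    def test_ten_homozygous_snps_one_segment(self):
        positions = [100_000 * (j + 1) for j in range(10)]
        ds = make_dataset(np.zeros((1, 10), dtype=int), positions=positions)
        seg = roh.detect_roh(ds, roh.ROHParams(min_snps=5))
        assert len(seg) == 1
        row = seg.iloc[0]
        assert (row.start_bp, row.end_bp, row.n_snps) == (100_000, 1_000_000, 10)
        assert row.length_bp == 900_001

    def test_interior_heterozygote_kills_the_run(self):
        positions = [100_000 * (j + 1) for j in range(10)]
        g = np.zeros((1, 10), dtype=int)
        g[0, 4] = 1
        ds = make_dataset(g, positions=positions)
        seg = roh.detect_roh(ds, roh.ROHParams(min_snps=5))
        assert len(seg) == 0

    def test_gap_splits_runs(self):
        positions = [1, 100_001, 200_001, 1_300_002, 1_400_002, 1_500_002]
        ds = make_dataset(np.zeros((1, 6), dtype=int), positions=positions)
        params = roh.ROHParams(min_length_bp=100_000, max_gap_bp=1_000_000, min_snps=3)
        seg = roh.detect_roh(ds, params)
        assert len(seg) == 2
        assert seg["n_snps"].tolist() == [3, 3]

    def test_unsorted_markers_rejected(self):
        ds = make_dataset(np.zeros((1, 3), dtype=int), positions=[300, 100, 200])
        with pytest.raises(ValueError, match="sorted"):
            roh.detect_roh(ds, roh.ROHParams(min_snps=1))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_strings(self, seed):
        rng = np.random.default_rng(seed)
        params = roh.ROHParams(
            min_length_bp=300_000, max_gap_bp=500_000, min_density_bp_per_snp=200_000,
            min_snps=4,
        )
        for _ in range(60):
            m = rng.integers(5, 51)
            g = rng.choice([0, 1, 2, MISSING], size=(1, m), p=[0.4, 0.15, 0.4, 0.05])
            positions = np.sort(rng.choice(5_000_000, size=m, replace=False) + 1)
            ds = make_dataset(g, positions=positions.tolist())
            got = roh.detect_roh(ds, params)
            expected = brute_force_roh(g[0], positions, params, params.min_snps)
            assert [
                (r.start_bp, r.end_bp, r.n_snps) for r in got.itertuples()
            ] == expected

    def test_tightening_thresholds_never_adds_segments(self):
        rng = np.random.default_rng(99)
        g = rng.choice([0, 1, 2], size=(3, 200), p=[0.45, 0.1, 0.45])
        positions = np.sort(rng.choice(20_000_000, size=200, replace=False) + 1).tolist()
        ds = make_dataset(g, positions=positions)
        base = roh.detect_roh(ds, roh.ROHParams(min_length_bp=200_000, min_snps=3,
                                                min_density_bp_per_snp=1e9))
        for min_snps, min_len in [(5, 200_000), (3, 500_000), (8, 1_000_000)]:
            tighter = roh.detect_roh(
                ds, roh.ROHParams(min_length_bp=min_len, min_snps=min_snps,
                                  min_density_bp_per_snp=1e9)
            )
            assert len(tighter) <= len(base)
            base_keys = {(r.sample_id, r.start_bp, r.end_bp) for r in base.itertuples()}
            assert all(
                (r.sample_id, r.start_bp, r.end_bp) in base_keys for r in tighter.itertuples()
            )


class TestClassify:
    def test_single_segment_share_is_100(self):
        seg = roh.detect_roh(
            make_dataset(np.zeros((1, 10), dtype=int)), roh.ROHParams(min_snps=5)
        )
        labeled, summary = roh.classify_roh(seg)
        assert summary.loc[summary["n_roh"] > 0, "share_pct"].tolist() == [100.0]

    def test_class_boundaries(self):
        scheme = roh.LengthClassScheme()
        lengths = np.array([1.0, 2.0, 2.5, 16.0, 16.5]) * 1_000_000
        assert scheme.assign(lengths).tolist() == ["0-2", "0-2", "2-4", "8-16", ">16"]

    def test_published_class_shares_recomputed(self):
        for breed, expect_first in [("CWD", 38.053), ("GW", 83.276)]:
            counts = [c for c in ROH_CLASS_SUMMARY[breed]["counts"] if c is not None]
            shares = roh.class_shares(counts)
            assert shares[0] == pytest.approx(expect_first, abs=6e-4)


class TestFroh:
    def test_no_segments_gives_zero(self):
        import pandas as pd

        seg = roh.detect_roh(make_dataset(np.ones((1, 10), dtype=int)),
                             roh.ROHParams(min_snps=5))
        res = roh.froh(seg, 1_000_000,
                       samples=pd.DataFrame({"sample_id": ["s0"], "group": ["g1"]}))
        assert (res.per_sample.drop(columns="sample_id") == 0).all().all()

    def test_simple_ratio(self):
        import pandas as pd

        seg = pd.DataFrame(
            [("s0", "1", 1, 21_995_340, 100, 21_995_340)],
            columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"],
        )
        res = roh.froh(seg, 2_199_534_000)
        assert res.per_sample["froh_total"].iloc[0] == pytest.approx(0.01)

    def test_froh_ge_nonincreasing_in_threshold(self, two_pop_ds):
        from canid.genotype_io import genome_span
        from canid.simulate import implant_roh

        ds, _ = two_pop_ds
        noisy, _ = implant_roh(ds.subset_samples(np.arange(10)), 0.08, seed=5)
        seg = roh.detect_roh(noisy, roh.ROHParams(min_snps=10))
        total, _ = genome_span(noisy)
        res = roh.froh(seg, total, samples=noisy.samples)
        cols = [f"froh_ge_{x:g}" for x in (0, 2, 4, 8, 16)]
        vals = res.per_sample[cols].to_numpy()
        assert (np.diff(vals, axis=1) <= 1e-12).all()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_cumulative_reconstruction_of_published_cwd_column(self):
        row = ROH_CLASS_SUMMARY["CWD"]
        got = roh.froh_from_class_summary(
            row["counts"], row["mean_length_mbp"], row["n_animals"], AUTOSOME_LENGTH_MBP
        )
        expected = np.asarray(row["froh_pct"])
        assert np.all(np.abs(got - expected) < 0.1)  # within 0.1 percentage points

    def test_per_class_mode_differs_from_cumulative(self):
        import pandas as pd

        seg = pd.DataFrame(
            [
                ("s0", "1", 1, 3_000_000, 50, 3_000_000),
                ("s0", "2", 1, 20_000_000, 300, 20_000_000),
            ],
            columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"],
        )
        cum = roh.froh(seg, 100_000_000, mode="cumulative").per_sample
        lit = roh.froh(seg, 100_000_000, mode="per_class").per_sample
        # cumulative >= per-class at the 2 Mbp threshold (long segment included)
        assert cum["froh_ge_2"].iloc[0] == pytest.approx(0.23)
        assert lit["froh_ge_2"].iloc[0] == pytest.approx(0.03)
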