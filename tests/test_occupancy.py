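"""Clonal filtering, fragment-size estimation, read adjustment, coverage and
quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from nucdyn.io import OccupancyTrack, ReadSet
from nucdyn.occupancy import (
    FragmentSizeError,
    adjust_reads,
    clonal_max_copies,
    compute_coverage,
    estimate_fragment_size,
    quantile_normalize,
    remove_clonal_reads,
)

SIZES = {"chr1": 10_000}


def _reads(rows, paired=False):
    return ReadSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "strand"]), paired=paired)


class TestClonalFilter:
    def test_singletons_untouched(self):
        rs = _reads([("chr1", i * 10, i * 10 + 50, "+") for i in range(20)])
        out, report = remove_clonal_reads(rs, SIZES)
        assert report["n_removed"] == 0
        pd.testing.assert_frame_equal(out.df, rs.df)

    def test_stack_truncated_at_poisson_bound(self):
        # oracle: direct summation of the Poisson pmf tail for k = 1, 2, ...
        lam, cutoff = 0.01, 1e-10

        def tail(k):  # P(X >= k) by explicit pmf summation
            pmf = np.exp(-lam)
            total = 1.0
            for j in range(k):
                total -= pmf
                pmf *= lam / (j + 1)
            return total

        k_expected = max(k for k in range(1, 60) if tail(k) >= cutoff)
        assert clonal_max_copies(lam, cutoff) == k_expected

        # a 50-deep stack on a genome tuned so lam = 0.01 is cut to k_expected
        sizes = {"chr1": 50_000}
        rows = [("chr1", 100, 150, "+")] * 50 + \
            [("chr1", 200 + 7 * i, 250 + 7 * i, "+") for i in range(450)]
        out, report = remove_clonal_reads(_reads(rows), sizes, cutoff=cutoff)
        assert report["lam"] == pytest.approx(0.01)
        kept = ((out.df["start"] == 100) & (out.df["strand"] == "+")).sum()
        assert kept == k_expected

    def test_opposite_strands_are_separate_stacks(self):
        sizes = {"chr1": 10}
        rows = [("chr1", 2, 5, "+")] * 3 + [("chr1", 2, 5, "-")] * 3
        out, report = remove_clonal_reads(_reads(rows), sizes, cutoff=0.05)
        plus = (out.df["strand"] == "+").sum()
        minus = (out.df["strand"] == "-").sum()
        assert plus == minus  # same bound applied independently per strand

    def test_empty_input(self):
        out, report = remove_clonal_reads(ReadSet.empty(), SIZES)
        assert len(out) == 0 and report["n_removed"] == 0

    def test_idempotent_on_synthetic_reads(self, small_reads):
        sizes = {"chr1": 60_000}
        once, _ = remove_clonal_reads(small_reads["wt"], sizes)
        twice, report = remove_clonal_reads(once, sizes)
        assert report["n_removed"] == 0
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestFragmentSize:
    def test_exact_for_noiseless_fragments(self):
        # fragments of length exactly 150 piled on a few dyads: the +/-
        # 5'-end cross-correlation peaks at the true length
        rng = np.random.default_rng(0)
        dyads = rng.integers(500, 9_500, size=25)
        rows = []
        for i, m in enumerate(rng.choice(dyads, size=600)):
            s, e = int(m) - 75, int(m) + 75
            if i % 2 == 0:
                rows.append(("chr1", s, s + 50, "+"))
            else:
                rows.append(("chr1", e - 50, e, "-"))
        assert estimate_fragment_size(_reads(rows), SIZES) == 150

    def test_within_5bp_of_generator_truth(self, small_truth, small_reads):
        est = estimate_fragment_size(small_reads["wt"], {"chr1": 60_000})
        assert abs(est - small_truth.config.fragment_len_mean) <= 5

    def test_single_strand_input_rejected(self):
        rows = [("chr1", i, i + 50, "+") for i in range(300)]
        with pytest.raises(FragmentSizeError, match="override"):
            estimate_fragment_size(_reads(rows), SIZES)

    def test_paired_fragments_use_their_own_length(self):
        rows = [("chr1", 100 + i, 260 + i, "+") for i in range(150)]
        assert estimate_fragment_size(_reads(rows, paired=True), SIZES) == 160


class TestAdjustReads:
    def test_strand_rules(self):
        rs = _reads([("chr1", 1000, 1050, "+"), ("chr1", 1100, 1150, "-")])
        adj = adjust_reads(rs, 150, SIZES)
        # "+": start + 75 = 1075 ; "-": (end-1) - 75 = 1074
        np.testing.assert_array_equal(adj.positions["chr1"], [1074, 1075])

    def test_paired_fragment_midpoint(self):
        rs = _reads([("chr1", 1000, 1150, "+")], paired=True)
        adj = adjust_reads(rs, 150, SIZES)
        np.testing.assert_array_equal(adj.positions["chr1"], [1075])

    def test_read_count_preserved_and_clipped(self):
        rs = _reads([("chr1", 9_990, 10_000, "+"), ("chr1", 0, 10, "-")])
        adj = adjust_reads(rs, 150, SIZES)
        assert len(adj) == 2
        assert adj.positions["chr1"].max() <= 9_999
        assert adj.positions["chr1"].min() >= 0


class TestCoverage:
    def test_single_position_footprint(self):
        rs = _reads([("chr1", 1000, 1050, "+")])
        track = compute_coverage(adjust_reads(rs, 150, SIZES), SIZES,
                                 half_width=73)
        v = track.values["chr1"]
        assert v[1002] == 1 and v[1148] == 1
        assert v[1001] == 0 and v[1149] == 0
        assert v.sum() == 147

    def test_zero_halfwidth_is_positional_histogram(self):
        rs = _reads([("chr1", 10, 60, "+"), ("chr1", 10, 60, "+")])
        track = compute_coverage(adjust_reads(rs, 100, SIZES), SIZES,
                                 half_width=0)
        v = track.values["chr1"]
        assert v[60] == 2 and v.sum() == 2

    def test_mass_conservation_oracle(self, small_reads):
        # genome total = sum over reads of their clipped footprint length,
        # counted directly and independently
        sizes = {"chr1": 60_000}
        adj = adjust_reads(small_reads["wt"], 150, sizes)
        w = 73
        track = compute_coverage(adj, sizes, half_width=w)
        expected = sum(
            min(p + w + 1, 60_000) - max(p - w, 0)
            for p in adj.positions["chr1"]
        )
        assert track.values["chr1"].sum() == expected


class TestQuantileNormalize:
    def test_identical_tracks_are_fixed_point(self):
        t = OccupancyTrack({"chr1": np.array([1.0, 5.0, 2.0])})
        u = OccupancyTrack({"chr1": np.array([1.0, 5.0, 2.0])})
        out = quantile_normalize([t, u])
        for o in out:
            np.testing.assert_array_equal(o.values["chr1"], [1.0, 5.0, 2.0])
            assert o.normalized == "quantile"

    def test_toy_rank_mean(self):
        a = OccupancyTrack({"chr1": np.array([1.0, 2.0, 3.0])})
        b = OccupancyTrack({"chr1": np.array([2.0, 4.0, 6.0])})
        out = quantile_normalize([a, b])
        np.testing.assert_array_equal(out[0].values["chr1"], [1.5, 3.0, 4.5])
        np.testing.assert_array_equal(out[1].values["chr1"], [1.5, 3.0, 4.5])

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=300))
    def test_sorted_multisets_identical(self, values):
        rng = np.random.default_rng(1)
        a = np.asarray(values, dtype=float)
        b = rng.poisson(5, size=len(a)).astype(float)
        out = quantile_normalize([
            OccupancyTrack({"chr1": a}), OccupancyTrack({"chr1": b})])
        sa = np.sort(out[0].values["chr1"])
        sb = np.sort(out[1].values["chr1"])
        np.testing.assert_array_equal(sa, sb)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(10, 500).astype(float)
        b = rng.poisson(20, 500).astype(float)
        out = quantile_normalize([
            OccupancyTrack({"chr1": a}), OccupancyTrack({"chr1": b})])
        oa = out[0].values["chr1"]
        assert ((a[:, None] < a[None, :]) <= (oa[:, None] <= oa[None, :])).all()

    def test_mean_and_sd_equal_across_samples(self, default_fit):
        # the sorted multisets are identical exactly; mean/SD agree to the
        # summation-order floating rounding
        tracks = list(default_fit.tracks.values())
        np.testing.assert_array_equal(np.sort(tracks[0].concatenated()),
                                      np.sort(tracks[1].concatenated()))
        assert tracks[0].genome_mean() == pytest.approx(
            tracks[1].genome_mean(), rel=1e-12)
        assert tracks[0].genome_sd() == pytest.approx(
            tracks[1].genome_sd(), rel=1e-12)

    def test_average_ties_variant(self):
        a = OccupancyTrack({"chr1": np.array([1.0, 1.0, 2.0])})
        b = OccupancyTrack({"chr1": np.array([1.0, 2.0, 3.0])})
        out = quantile_normalize([a, b], ties="average")
        # sample A's tied pair shares the mean of the first two reference values
        ref = np.sort((np.sort(a.values["chr1"]) + np.sort(b.values["chr1"])) / 2)
        np.testing.assert_allclose(out[0].values["chr1"],
                                   [ref[:2].mean(), ref[:2].mean(), ref[2]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different"):
            quantile_normalize([
                OccupancyTrack({"chr1": np.zeros(3)}),
                OccupancyTrack({"chr1": np.zeros(4)})])
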