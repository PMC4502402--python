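"""Nucleosome calling, Poisson differential signal, BH FDR, and the
classification of dynamic nucleosomes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nucdyn import NucleosomeDynamics, SyntheticConfig
from nucdyn.io import OccupancyTrack
from nucdyn.occupancy import (adjust_reads, compute_coverage,
                              quantile_normalize, remove_clonal_reads,
                              estimate_fragment_size)
from nucdyn.dynamics import (
    DynamicsConfig,
    bh_fdr,
    call_nucleosomes,
    differential_signal,
    dynamic_fraction,
    match_and_classify,
)
from nucdyn.simulate import build_truth, sample_reads
from conftest import small_config


def poisson_tail_oracle(b, a, upper):
    """P(X >= b) or P(X <= b) for X ~ Poisson(a) by explicit pmf summation."""
    pmf = np.exp(-a)
    total = 0.0
    k = 0
    while True:
        if (k >= b) if upper else (k <= b):
            total += pmf
        if k > b + 60 * (1 + np.sqrt(a)):
            break
        pmf *= a / (k + 1)
        k += 1
    return total


class TestBhFdr:
    def test_closed_form_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_stepup_enumeration(self, pvals):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, m * p[order[rank]] / (rank + 1))
                adj[order[rank]] = running
            return adj

        np.testing.assert_allclose(bh_fdr(pvals), oracle(pvals), atol=1e-12)


class TestDifferentialSignal:
    def test_equal_tracks_never_significant(self):
        v = np.array([0.0, 1.0, 5.0, 20.0, 100.0])
        p = differential_signal(OccupancyTrack({"c": v.copy()}),
                                OccupancyTrack({"c": v.copy()}))["c"]
        # the two-sided p at b == a always contains the central mass
        assert (p > 0.3).all()

    def test_matches_pmf_summation_oracle(self):
        a, b = 10.0, 30.0
        p = differential_signal(OccupancyTrack({"c": np.array([a])}),
                                OccupancyTrack({"c": np.array([b])}))["c"][0]
        assert p == pytest.approx(2 * poisson_tail_oracle(30, 10.0, True),
                                  abs=1e-12)

    def test_zero_vs_zero_is_one(self):
        p = differential_signal(OccupancyTrack({"c": np.zeros(3)}),
                                OccupancyTrack({"c": np.zeros(3)}))["c"]
        np.testing.assert_array_equal(p, [1.0, 1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            differential_signal(OccupancyTrack({"c": np.zeros(3)}),
                                OccupancyTrack({"c": np.zeros(4)}))


def _deep_track(dyads, weights=None, depth=40_000, seed=0, chrom_len=6_000,
                fuzziness=20.0):
    """Coverage track plus adjusted reads for hand-planted dyads."""
    rng = np.random.default_rng(seed)
    weights = np.ones(len(dyads)) if weights is None else np.asarray(weights)
    idx = rng.choice(len(dyads), size=depth, p=weights / weights.sum())
    pos = np.clip(np.rint(np.asarray(dyads)[idx]
                          + rng.normal(0, fuzziness, depth)),
                  0, chrom_len - 1).astype(np.int64)
    from nucdyn.occupancy import AdjustedReads

    adj = AdjustedReads({"chr1": np.sort(pos)})
    track = compute_coverage(adj, {"chr1": chrom_len})
    return track, adj


class TestCallNucleosomes:
    def test_single_dyad_recovered_within_5bp(self):
        track, adj = _deep_track([3_000])
        calls = call_nucleosomes(track, adj)
        assert len(calls) == 1
        assert abs(int(calls["summit"].iloc[0]) - 3_000) <= 5
        assert calls["fuzziness"].iloc[0] == pytest.approx(20.0, abs=3.0)

    def test_two_dyads_165_apart_give_disjoint_summit_spans(self):
        track, adj = _deep_track([3_000, 3_165])
        calls = call_nucleosomes(track, adj).sort_values("summit")
        assert len(calls) == 2
        first, second = calls.iloc[0], calls.iloc[1]
        assert first["end"] <= second["summit"]
        assert second["start"] > first["summit"]

    def test_zero_track_gives_no_calls(self):
        track = OccupancyTrack({"chr1": np.zeros(1_000)})
        assert len(call_nucleosomes(track)) == 0

    def test_summits_respect_minimum_spacing(self, default_fit):
        for calls in default_fit.calls.values():
            for _chrom, sub in calls.groupby("chrom"):
                gaps = np.diff(np.sort(sub["summit"].to_numpy()))
                assert (gaps >= 147).all()


def _fit_pair(truth, config=DynamicsConfig()):
    sizes = truth.annotation.chrom_sizes
    tracks, adjs = [], []
    for cond in truth.conditions:
        rs, _ = remove_clonal_reads(sample_reads(truth, cond), sizes)
        frag = estimate_fragment_size(rs, sizes)
        adj = adjust_reads(rs, frag, sizes)
        adjs.append(adj)
        tracks.append(compute_coverage(adj, sizes, sample=cond))
    tracks = quantile_normalize(tracks)
    calls = [call_nucleosomes(t, a) for t, a in zip(tracks, adjs)]
    pvals = differential_signal(tracks[0], tracks[1])
    dyn = match_and_classify(calls[0], calls[1], pvals, config,
                             adjusted_wt=adjs[0], adjusted_mut=adjs[1],
                             track_wt=tracks[0], track_mut=tracks[1])
    return calls, dyn


class TestMatchAndClassify:
    def test_identical_reads_yield_no_dynamics(self, small_truth):
        sizes = small_truth.annotation.chrom_sizes
        rs, _ = remove_clonal_reads(sample_reads(small_truth, "wt"), sizes)
        adj = adjust_reads(rs, 150, sizes)
        track = compute_coverage(adj, sizes)
        calls = call_nucleosomes(track, adj)
        pvals = differential_signal(track, track)
        dyn = match_and_classify(calls, calls.copy(), pvals,
                                 adjusted_wt=adj, adjusted_mut=adj)
        assert dynamic_fraction(dyn, calls) == 0.0

    def test_matching_is_partial_injection(self, default_fit):
        dyn = default_fit.dynamics
        matched_wt = dyn.loc[dyn["call_wt"] >= 0, "call_wt"]
        matched_mut = dyn.loc[dyn["call_mut"] >= 0, "call_mut"]
        assert matched_wt.is_unique and matched_mut.is_unique

    def test_planted_occupancy_gain_detected_at_high_depth(self):
        # mechanism check at depth where a 2x change is identifiable:
        # 3 of 30 nucleosomes doubled, ~130 reads/nucleosome
        cfg = small_config(depth=400_000, perturbed_fraction=0.25,
                           classes=("occupancy",), seed=13)
        truth = build_truth(cfg)
        calls, dyn = _fit_pair(truth)
        planted = truth.dyads["wt"]
        sel = planted["gene_id"].isin(truth.genes_with_label("occupancy"))
        sites = planted[sel & (planted["role"] == "-1")]
        hits = 0
        for _i, site in sites.iterrows():
            anchor = dyn["summit_wt"].where(dyn["summit_wt"] >= 0,
                                            dyn["summit_mut"])
            near = dyn[(dyn["chrom"] == site["chrom"])
                       & (anchor >= site["pos"] - 74)
                       & (anchor <= site["pos"] + 74)
                       & (dyn["category"] == "occupancy_change")]
            hits += len(near) > 0
        assert hits >= 0.8 * len(sites)

    def test_planted_shifts_recovered_with_correct_delta(self):
        cfg = small_config(depth=400_000, perturbed_fraction=0.25,
                           classes=("shift",), seed=17)
        truth = build_truth(cfg)
        calls, dyn = _fit_pair(truth)
        wt, mut = truth.dyads["wt"], truth.dyads["mut"]
        moved = wt[(mut["pos"] - wt["pos"]).abs() > 0].copy()
        moved["pos_mut"] = mut.loc[moved.index, "pos"]

        def _called(table, chrom, pos, tol=30):
            sub = table[(table["chrom"] == chrom)
                        & (table["summit"] >= pos - tol)
                        & (table["summit"] <= pos + tol)]
            return len(sub) > 0

        # condition on sites the caller resolves cleanly in both conditions:
        # weak nucleosomes fall below the genome-mean summit threshold, and a
        # shifted +1 can merge with the first gene-body nucleosome when their
        # spacing drops below one nucleosome width
        visible = moved[[
            _called(calls[0], r.chrom, r.pos)
            and _called(calls[1], r.chrom, r.pos_mut)
            for r in moved.itertuples()]]
        assert len(visible) >= max(4, 0.5 * len(moved))
        deltas = []
        for _i, site in visible.iterrows():
            near = dyn[(dyn["chrom"] == site["chrom"])
                       & (dyn["summit_wt"] >= site["pos"] - 74)
                       & (dyn["summit_wt"] <= site["pos"] + 74)
                       & (dyn["summit_mut"] >= 0)]
            if len(near):
                deltas.append(abs(int(near["delta_summit"].iloc[0])))
        assert len(deltas) >= 0.8 * len(visible)
        within = sum(abs(d - cfg.perturbation.shift_bp) <= 10 for d in deltas)
        assert within >= 0.8 * len(deltas)

    def test_label_swap_symmetry(self):
        # swapping the condition labels maps gains to losses and preserves
        # the dynamic set at >= 95% overlap
        cfg = small_config(depth=400_000, perturbed_fraction=0.25, seed=19)
        truth = build_truth(cfg)
        sizes = truth.annotation.chrom_sizes
        tracks, adjs = [], []
        for cond in truth.conditions:
            rs, _ = remove_clonal_reads(sample_reads(truth, cond), sizes)
            adj = adjust_reads(rs, estimate_fragment_size(rs, sizes), sizes)
            adjs.append(adj)
            tracks.append(compute_coverage(adj, sizes, sample=cond))
        tracks = quantile_normalize(tracks)
        calls = [call_nucleosomes(t, a) for t, a in zip(tracks, adjs)]
        fwd = match_and_classify(
            calls[0], calls[1], differential_signal(tracks[0], tracks[1]),
            adjusted_wt=adjs[0], adjusted_mut=adjs[1],
            track_wt=tracks[0], track_mut=tracks[1])
        rev = match_and_classify(
            calls[1], calls[0], differential_signal(tracks[1], tracks[0]),
            adjusted_wt=adjs[1], adjusted_mut=adjs[0],
            track_wt=tracks[1], track_mut=tracks[0])
        set_a = {(r.chrom, r.summit_wt, r.summit_mut) for r in fwd.itertuples()}
        set_b = {(r.chrom, r.summit_mut, r.summit_wt) for r in rev.itertuples()}
        assert set_a and set_b
        overlap = len(set_a & set_b) / len(set_a | set_b)
        assert overlap >= 0.95
        gains_fwd = (fwd["direction"] == "gain").sum()
        losses_rev = (rev["direction"] == "loss").sum()
        assert abs(int(gains_fwd) - int(losses_rev)) <= max(
            2, 0.05 * max(gains_fwd, losses_rev))

    def test_recovery_nondecreasing_in_depth(self):
        # sensitivity for planted promoter shifts grows (or holds) with
        # sequencing depth
        recovered = []
        for depth in (100_000, 200_000, 400_000):
            cfg = small_config(depth=depth, perturbed_fraction=0.25,
                               classes=("shift",), seed=29)
            truth = build_truth(cfg)
            _calls, dyn = _fit_pair(truth)
            wt, mut = truth.dyads["wt"], truth.dyads["mut"]
            moved = wt[(mut["pos"] - wt["pos"]).abs() > 0]
            hits = 0
            for r in moved.itertuples():
                near = dyn[(dyn["chrom"] == r.chrom)
                           & ((dyn["summit_wt"] - r.pos).abs() <= 74)
                           & (dyn["summit_mut"] >= 0)]
                hits += len(near) > 0
            recovered.append(hits)
        assert recovered[0] <= recovered[1] <= recovered[2]
        assert recovered[-1] > 0

    def test_dynamic_fraction_arithmetic(self):
        calls = pd.DataFrame({"chrom": ["c"] * 1000})
        dyn = pd.DataFrame({"chrom": ["c"] * 37})
        assert dynamic_fraction(dyn, calls) == pytest.approx(0.037)
        with pytest.raises(ValueError):
            dynamic_fraction(dyn, calls.iloc[:0])

    def test_empty_inputs_give_empty_result(self):
        empty = pd.DataFrame(columns=["chrom", "summit", "start", "end",
                                      "summit_occupancy", "fuzziness",
                                      "n_reads"])
        out = match_and_classify(empty, empty.copy(), {})
        assert len(out) == 0
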