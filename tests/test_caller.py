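from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

import strandloop as sl
from strandloop.caller import binom_two_sided

from _oracle import brute_bh, brute_binom_two_sided, brute_call_pipeline
from test_coverage import frags_from_records


# ------------------------------------------------------------- binomial test


class TestStrandImbalanceTest:
    def test_balanced_is_one(self):
        assert sl.strand_imbalance_test(10, 10) == 1.0

    def test_no_data_is_one(self):
        assert sl.strand_imbalance_test(0, 0) == 1.0

    def test_30_10_matches_brute_force(self):
        p = sl.strand_imbalance_test(30, 10)
        assert p == pytest.approx(brute_binom_two_sided(30, 40), abs=1e-14)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            sl.strand_imbalance_test(-1, 5)

    @settings(deadline=None, max_examples=80)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_symmetric_and_matches_oracle(self, k, m):
        p = sl.strand_imbalance_test(k, m)
        assert p == sl.strand_imbalance_test(m, k)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(brute_binom_two_sided(k, k + m), rel=1e-10, abs=1e-300)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 80), st.integers(0, 80))
    def test_matches_scipy_binomtest(self, k, m):
        if k + m == 0:
            return
        ours = sl.strand_imbalance_test(k, m)
        ref = binomtest(k, k + m, 0.5, alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_vectorized_agrees_with_scalar(self):
        ks = np.array([0, 3, 30, 50])
        ms = np.array([0, 3, 10, 5])
        vec = binom_two_sided(ks, ms)
        for k, m, p in zip(ks, ms, vec):
            assert p == sl.strand_imbalance_test(int(k), int(m))


# ----------------------------------------------------------------------- BH


class TestBhAdjust:
    def test_worked_example(self):
        q = sl.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_single(self):
        assert sl.bh_adjust([1.0]).tolist() == [1.0]

    def test_all_equal(self):
        np.testing.assert_allclose(sl.bh_adjust([0.3] * 5), [0.3] * 5)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            sl.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            sl.bh_adjust([-0.1])

    def test_preserves_input_order(self):
        p = [0.04, 0.001, 0.9, 0.2]
        q = sl.bh_adjust(p)
        assert np.argmin(q) == 1

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_statsmodels_and_oracle(self, pvals):
        q = sl.bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        np.testing.assert_allclose(q, brute_bh(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-15).all()


# ----------------------------------------------------------- bin thresholds


def make_stats(plus_density, minus_density, q, pseudocount=1.0):
    log2r = np.log2(np.asarray(plus_density) + pseudocount) - np.log2(
        np.asarray(minus_density) + pseudocount
    )
    n = len(plus_density)
    return pd.DataFrame(
        {
            "chrom": ["chrT"] * n,
            "start": np.arange(n) * 500,
            "end": np.arange(n) * 500 + 500,
            "plus_density": plus_density,
            "minus_density": minus_density,
            "plus_count": (np.asarray(plus_density) * 10).astype(int),
            "minus_count": (np.asarray(minus_density) * 10).astype(int),
            "log2_ratio": log2r,
            "p_value": q,
            "q_value": q,
        }
    )


class TestCallRloopBins:
    def test_kept_example(self):
        stats = make_stats([50.0], [10.0], [0.001])
        assert stats.loc[0, "log2_ratio"] == pytest.approx(np.log2(51 / 11))
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig())) == 1

    def test_dropped_low_density(self):
        stats = make_stats([15.0], [3.0], [0.001])  # mean 9 <= 20
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig())) == 0

    def test_dropped_low_ratio(self):
        stats = make_stats([40.0], [25.0], [0.001])  # |log2(41/26)| = 0.66
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig())) == 0

    def test_density_exactly_20_rejected(self):
        stats = make_stats([20.0], [20.0], [0.0])
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig())) == 0

    def test_log2_exactly_one_accepted(self):
        # plus 63, minus 31: (63+1)/(31+1) = 2 exactly
        stats = make_stats([63.0], [31.0], [0.001])
        assert stats.loc[0, "log2_ratio"] == 1.0
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig())) == 1

    def test_q_exactly_max_accepted(self):
        stats = make_stats([63.0], [31.0], [0.05])
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig())) == 1

    def test_density_mode_switch(self):
        stats = make_stats([30.0], [5.0], [0.001])  # mean 17.5, sum 35, max 30
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig(density_mode="mean"))) == 0
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig(density_mode="sum"))) == 1
        assert len(sl.call_rloop_bins(stats, sl.CallerConfig(density_mode="max"))) == 1


class TestMergeRloopBins:
    def test_mean_density_over_bins(self):
        stats = make_stats([40.0, 60.0], [10.0, 10.0], [0.001, 0.002])
        stats["start"] = [0, 250]
        stats["end"] = [500, 750]
        calls = sl.merge_rloop_bins(stats, sl.CallerConfig())
        assert len(calls) == 1
        assert calls.loc[0, "density"] == pytest.approx((30 + 50) / 2)
        assert calls.loc[0, "displaced_strand"] == "+"
        assert calls.loc[0, "n_bins"] == 2
        assert calls.loc[0, "min_q"] == 0.001

    def test_opposite_directions_never_merge(self):
        stats = make_stats([50.0, 10.0], [10.0, 50.0], [0.001, 0.001])
        stats["start"] = [0, 250]
        stats["end"] = [500, 750]
        calls = sl.merge_rloop_bins(stats, sl.CallerConfig())
        assert len(calls) == 2
        assert set(calls["displaced_strand"]) == {"+", "-"}

    def test_single_bin_identity(self):
        stats = make_stats([50.0], [10.0], [0.001])
        calls = sl.merge_rloop_bins(stats, sl.CallerConfig())
        assert (calls.loc[0, "start"], calls.loc[0, "end"]) == (0, 500)

    def test_empty_input(self):
        calls = sl.merge_rloop_bins(make_stats([], [], []), sl.CallerConfig())
        assert len(calls) == 0


# --------------------------------------------------------------- config


class TestCallerConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bin_width": 0},
            {"bin_step": 0},
            {"bin_step": 600},
            {"max_q": 0.0},
            {"max_q": 1.5},
            {"pseudocount": 0.0},
            {"merge_gap": -1},
            {"density_mode": "median"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            sl.CallerConfig(**kwargs)


# ------------------------------------------------------------- end to end


def test_null_simulation_near_zero_calls():
    asm = sl.GenomeAssembly({"chr1": 100_000})
    cfg = sl.SimConfig(assembly=asm, features=[], background_depth=30.0, seed=3)
    frags, _ = sl.simulate_condition(cfg, "control")
    peaks = sl.IntervalSet.from_records([("chr1", 0, 100_000)], assembly=asm)
    res = sl.call_pipeline(frags, peaks, None, asm, sl.CallerConfig())
    assert len(res.calls) <= 1


def test_planted_rloop_single_call(planted_sim):
    cfg, peaks = planted_sim
    frags, truth = sl.simulate_condition(cfg, "control")
    res = sl.call_pipeline(frags, peaks, None, cfg.assembly, sl.CallerConfig())
    assert len(res.calls) == 1
    call = res.calls.iloc[0]
    assert call["chrom"] == "chr1"
    assert call["start"] < 51_000 and call["end"] > 50_000  # overlaps the plant
    assert call["displaced_strand"] == "+"


def test_call_pipeline_fragment_order_invariance(planted_sim):
    cfg, peaks = planted_sim
    frags, _ = sl.simulate_condition(cfg, "control")
    shuffled_plus = sl.IntervalSet(
        frags.plus.df.sample(frac=1.0, random_state=1), assembly=cfg.assembly, validate=False
    )
    shuffled = sl.StrandedFragmentSet(
        plus=shuffled_plus, minus=frags.minus, assembly=cfg.assembly
    )
    a = sl.call_pipeline(frags, peaks, None, cfg.assembly)
    b = sl.call_pipeline(shuffled, peaks, None, cfg.assembly)
    pd.testing.assert_frame_equal(a.calls, b.calls)
    pd.testing.assert_frame_equal(a.bin_stats, b.bin_stats)


def test_threshold_monotonicity(planted_sim):
    cfg, peaks = planted_sim
    frags, _ = sl.simulate_condition(cfg, "control")
    base = sl.call_pipeline(frags, peaks, None, cfg.assembly, sl.CallerConfig())
    for stricter in (
        sl.CallerConfig(min_density=40.0),
        sl.CallerConfig(min_abs_log2_ratio=1.5),
        sl.CallerConfig(max_q=0.001),
    ):
        res = sl.call_pipeline(frags, peaks, None, cfg.assembly, stricter)
        assert len(res.calls) <= len(base.calls)


def test_blacklisted_feature_not_called(planted_sim):
    cfg, peaks = planted_sim
    frags, _ = sl.simulate_condition(cfg, "control")
    blacklist = sl.IntervalSet.from_records([("chr1", 49_000, 52_000)], assembly=cfg.assembly)
    res = sl.call_pipeline(frags, peaks, blacklist, cfg.assembly)
    assert len(res.calls) == 0


def test_every_call_overlaps_a_passing_bin(planted_sim):
    cfg, peaks = planted_sim
    frags, _ = sl.simulate_condition(cfg, "control")
    res = sl.call_pipeline(frags, peaks, None, cfg.assembly)
    sig = sl.call_rloop_bins(res.bin_stats, res.config)
    for call in res.calls.itertuples(index=False):
        hit = (
            (sig["chrom"] == call.chrom)
            & (sig["start"] < call.end)
            & (sig["end"] > call.start)
        )
        assert hit.any()


# ------------------------------------------------------------------ oracle


def test_pipeline_matches_brute_force_oracle():
    """Full-pipeline equivalence against an independent reimplementation."""
    asm = sl.GenomeAssembly({"chrA": 60_000, "chrB": 40_000})
    feats = [
        sl.PlantedFeature("chrA", 10_000, 11_000, "rloop", "+", 4.0, 40.0, name="a1"),
        sl.PlantedFeature("chrA", 30_000, 30_800, "rloop", "-", 5.0, 50.0, name="a2"),
        sl.PlantedFeature("chrB", 5_000, 6_000, "bubble", "+", 1.0, 40.0, name="b1"),
        sl.PlantedFeature("chrB", 20_000, 21_000, "rloop", "+", 3.0, 45.0, name="b2"),
    ]
    cfg = sl.SimConfig(assembly=asm, features=feats, background_depth=2.0, seed=42)
    frags, _ = sl.simulate_condition(cfg, "control")
    peaks = sl.IntervalSet.from_records(
        [("chrA", 9_000, 12_000), ("chrA", 29_000, 32_000), ("chrB", 4_000, 7_000),
         ("chrB", 19_500, 21_500)],
        assembly=asm,
    )
    blacklist = sl.IntervalSet.from_records([("chrB", 0, 2_000)], assembly=asm)
    res = sl.call_pipeline(frags, peaks, blacklist, asm, sl.CallerConfig())

    def to_dict(iset):
        out = {}
        for iv in iset:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return out

    oracle_calls, oracle_stats = brute_call_pipeline(
        to_dict(frags.plus),
        to_dict(frags.minus),
        to_dict(peaks),
        to_dict(blacklist),
        dict(asm),
    )
    assert len(res.bin_stats) == len(oracle_stats)
    ours = res.bin_stats.sort_values(["chrom", "start"]).reset_index(drop=True)
    theirs = pd.DataFrame(oracle_stats).sort_values(["chrom", "start"]).reset_index(drop=True)
    np.testing.assert_array_equal(ours["plus_count"], theirs["plus_count"])
    np.testing.assert_allclose(ours["plus_density"], theirs["plus_density"], atol=1e-9)
    np.testing.assert_allclose(ours["q_value"], theirs["q_value"], atol=1e-12)
    # call regions and per-call summaries identical
    got = {
        (c.chrom, c.start, c.end, c.displaced_strand): (c.density, c.n_bins, c.min_q)
        for c in res.calls.itertuples(index=False)
    }
    want = {
        (c["chrom"], c["start"], c["end"], c["displaced_strand"]): (
            c["density"], c["n_bins"], c["min_q"],
        )
        for c in oracle_calls
    }
    assert got.keys() == want.keys()
    for key in got:
        assert got[key][0] == pytest.approx(want[key][0], abs=1e-9)
        assert got[key][1] == want[key][1]
        assert got[key][2] == pytest.approx(want[key][2], abs=1e-12)
    assert len(res.calls) >= 3  # the three planted R-loops were found


# ------------------------------------------------------------------ census


class TestCensus:
    def _frags(self, asm, seed=5, planted=()):
        feats = [
            sl.PlantedFeature(c, s, e, "rloop", strand, 8.0, 30.0, name=f"f{i}")
            for i, (c, s, e, strand) in enumerate(planted)
        ]
        cfg = sl.SimConfig(assembly=asm, features=feats, background_depth=3.0, seed=seed)
        frags, _ = sl.simulate_condition(cfg, "control")
        return frags

    def test_balanced_near_zero(self):
        asm = sl.GenomeAssembly({"chr1": 200_000})
        frags = self._frags(asm)
        res = sl.imbalanced_bin_census(frags, asm, bin_width=2000)
        assert res.n_imbalanced == 0

    def test_planted_regions_counted(self):
        asm = sl.GenomeAssembly({"chr1": 200_000})
        planted = [("chr1", 10_000 + i * 18_000, 12_000 + i * 18_000, "+") for i in range(10)]
        frags = self._frags(asm, planted=planted)
        res = sl.imbalanced_bin_census(frags, asm, bin_width=2000)
        assert res.n_imbalanced == 10

    def test_strand_swap_symmetry(self):
        asm = sl.GenomeAssembly({"chr1": 100_000})
        planted = [("chr1", 20_000, 22_000, "+"), ("chr1", 60_000, 62_000, "-")]
        frags = self._frags(asm, planted=planted)
        a = sl.imbalanced_bin_census(frags, asm, bin_width=2000)
        b = sl.imbalanced_bin_census(frags.swap_strands(), asm, bin_width=2000)
        assert a.n_imbalanced == b.n_imbalanced
        np.testing.assert_array_equal(
            a.table["log2_ratio"].to_numpy(), -b.table["log2_ratio"].to_numpy()
        )
        np.testing.assert_array_equal(a.table["q_value"], b.table["q_value"])
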