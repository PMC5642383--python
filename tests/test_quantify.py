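"""Mutation counting, group aggregation, signal binning, pairing, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regmut import (
    FeatureTrack,
    aggregate_group,
    correlate_feature,
    count_mutations_per_window,
    make_windows,
    partition_paired_mutations,
    signal_per_window,
)
from regmut import simulate
from conftest import make_catalog, uniform_catalog

MB = 1_000_000


class TestCountMutations:
    def test_empty_catalog_gives_zero_vector(self, two_windows):
        cat = make_catalog([], metadata=pd.DataFrame({"sample_id": ["s0"]}))
        dv = count_mutations_per_window(cat, two_windows)
        assert dv.values.tolist() == [0.0, 0.0]

    def test_half_open_window_boundaries(self, two_windows):
        cat = make_catalog([
            ("chr1", 10, "A", "T", "s0"),
            ("chr1", 999_999, "C", "G", "s0"),
            ("chr1", 1_000_000, "G", "A", "s0"),
        ])
        dv = count_mutations_per_window(cat, two_windows)
        assert dv.values.tolist() == [2.0, 1.0]

    def test_uniform_mutations_match_floor_division_histogram(self):
        ws = make_windows({"chr1": 10 * MB}, MB)
        cat, pos = uniform_catalog(1000, 10, seed=17)
        dv = count_mutations_per_window(cat, ws)
        oracle = np.bincount(pos // MB, minlength=10)
        np.testing.assert_array_equal(dv.values, oracle)

    def test_count_conservation_with_dropped_records(self):
        ws = make_windows({"chr1": 3 * MB}, MB)
        cat = make_catalog([
            ("chr1", 10, "A", "T", "s0"),
            ("chr2", 10, "A", "T", "s0"),        # chromosome with no windows
            ("chr1", 5 * MB, "A", "T", "s0"),    # beyond the last window
        ])
        dv = count_mutations_per_window(cat, ws)
        assert dv.values.sum() + dv.n_dropped == 3
        assert dv.n_dropped == 2

    def test_unknown_sample_raises(self, two_windows):
        cat = make_catalog([("chr1", 1, "A", "T", "s0")])
        with pytest.raises(KeyError, match="ghost"):
            count_mutations_per_window(cat, two_windows, ["ghost"])


class TestAggregateGroup:
    def test_single_sample_equals_per_sample_count(self, two_windows):
        cat = make_catalog([("chr1", 5, "A", "T", "s0"),
                            ("chr1", MB + 5, "A", "T", "s1")])
        dv = aggregate_group(cat, two_windows, lambda r: r.name == "s0")
        per = count_mutations_per_window(cat, two_windows, ["s0"])
        np.testing.assert_array_equal(dv.values, per.values)

    def test_group_sum_is_elementwise_sample_sum(self):
        ws = make_windows({"chr1": 5 * MB}, MB)
        cat0, _ = uniform_catalog(200, 5, seed=1, sample_id="s0")
        cat1, _ = uniform_catalog(300, 5, seed=2, sample_id="s1")
        rec = pd.concat([cat0.records, cat1.records], ignore_index=True)
        cat = make_catalog(list(rec.itertuples(index=False, name=None)))
        both = aggregate_group(cat, ws, lambda r: True)
        s0 = count_mutations_per_window(cat, ws, ["s0"])
        s1 = count_mutations_per_window(cat, ws, ["s1"])
        np.testing.assert_array_equal(both.values, s0.values + s1.values)
        assert both.n_samples == 2

    def test_dysplasia_grade_groups_conserve_counts(self):
        """Grade-subgrouped totals (17 ND / 3 LGD / 2 HGD samples) match the
        per-grade record counts by construction."""
        ws = make_windows({"chr1": 60 * MB}, MB)
        fm = simulate.gen_features(ws, [("t0", ["H3K4me1"])], seed=0)
        truth = simulate.SyntheticTruth(["t0_H3K4me1"], [0.5], seed=0)
        grades = ["ND"] * 17 + ["LGD"] * 3 + ["HGD"] * 2
        cat = simulate.gen_mutations(fm, truth, 22, seed=4, ws=ws,
                                     dysplasia=grades)
        for grade, n_samples in [("ND", 17), ("LGD", 3), ("HGD", 2)]:
            dv = aggregate_group(cat, ws, lambda r, g=grade: r["dysplasia"] == g)
            assert dv.n_samples == n_samples
            expected = len(cat.records[cat.records["sample_id"].isin(
                cat.metadata.index[cat.metadata["dysplasia"] == grade])])
            assert dv.values.sum() + dv.n_dropped == expected

    def test_empty_group_raises(self, two_windows):
        cat = make_catalog([("chr1", 1, "A", "T", "s0")])
        with pytest.raises(ValueError, match="no samples"):
            aggregate_group(cat, two_windows, lambda r: False)


class TestSignalPerWindow:
    def test_no_intervals_gives_zero_track(self, two_windows):
        vals = signal_per_window(pd.DataFrame(columns=["chrom", "start", "end"]),
                                 two_windows)
        assert vals.tolist() == [0.0, 0.0]

    def test_interval_spanning_one_window_score_sum(self, two_windows):
        iv = pd.DataFrame([("chr1", 0, MB, 5.0)],
                          columns=["chrom", "start", "end", "score"])
        vals = signal_per_window(iv, two_windows, mode="score_sum")
        assert vals.tolist() == [5.0, 0.0]

    def test_straddling_interval_splits_by_overlap(self, two_windows):
        # 30% in window 0, 70% in window 1
        iv = pd.DataFrame([("chr1", 700_000, 1_700_000, 10.0)],
                          columns=["chrom", "start", "end", "score"])
        vals = signal_per_window(iv, two_windows, mode="score_sum")
        np.testing.assert_allclose(vals, [3.0, 7.0])
        counts = signal_per_window(iv, two_windows, mode="read_count")
        assert counts.tolist() == [0.0, 1.0]  # midpoint at 1.2 Mb

    def test_score_sum_conservation_over_retained_windows(self):
        ws = make_windows({"chr1": 4 * MB}, MB)
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 4 * MB - 50_000, size=40)
        iv = pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + 50_000,
            "score": rng.random(40),
        })
        vals = signal_per_window(iv, ws, mode="score_sum")
        assert vals.sum() == pytest.approx(iv["score"].sum(), rel=1e-12)

    def test_negative_interval_length_raises(self, two_windows):
        iv = pd.DataFrame([("chr1", 100, 100, 1.0)],
                          columns=["chrom", "start", "end", "score"])
        with pytest.raises(ValueError, match="positive length"):
            signal_per_window(iv, two_windows, mode="score_sum")


class TestPartitionPaired:
    @staticmethod
    def _paired_catalog(pre_muts, can_muts):
        meta = pd.DataFrame({
            "sample_id": ["p0", "c0"],
            "cohort": ["precancer", "cancer"],
            "pair_id": ["pair0", "pair0"],
        })
        recs = [(c, p, r, a, "p0") for c, p, r, a in pre_muts]
        recs += [(c, p, r, a, "c0") for c, p, r, a in can_muts]
        return make_catalog(recs, meta)

    def test_identical_sets_are_all_common(self):
        muts = [("chr1", i, "A", "T") for i in range(5)]
        cat = self._paired_catalog(muts, muts)
        pre, common, can = partition_paired_mutations(cat, "pair0")
        assert len(pre) == 0 and len(can) == 0 and len(common) == 5

    def test_disjoint_sets_have_empty_common(self):
        cat = self._paired_catalog([("chr1", 1, "A", "T")],
                                   [("chr1", 2, "A", "T")])
        pre, common, can = partition_paired_mutations(cat, "pair0")
        assert len(common) == 0 and len(pre) == 1 and len(can) == 1

    def test_partition_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(40)
        pre = {("chr1", int(p), "A", "T") for p in rng.choice(10 * MB, 500, replace=False)}
        pre = sorted(pre)
        shared = [m for i, m in enumerate(pre) if i < 200]
        extra = [("chr1", int(p) + 10 * MB, "C", "G")
                 for p in rng.choice(MB, 150, replace=False)]
        cat = self._paired_catalog(pre, shared + extra)
        a, common, b = partition_paired_mutations(cat, "pair0")
        pre_set, can_set = set(pre), set(shared + extra)
        assert len(common) == len(pre_set & can_set) == 200
        assert len(a) == len(pre_set - can_set)
        assert len(b) == len(can_set - pre_set)
        assert len(a) + len(common) + len(b) == len(pre_set | can_set)

    def test_pair_with_wrong_sample_count_raises(self):
        cat = self._paired_catalog([("chr1", 1, "A", "T")], [])
        with pytest.raises(ValueError, match="expected exactly 2"):
            partition_paired_mutations(cat, "nope")


class TestCorrelateFeature:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).random(30)
        assert correlate_feature(x, x) == pytest.approx(1.0)
        assert correlate_feature(x, -x, method="pearson") == pytest.approx(-1.0)

    def test_spearman_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.random(20), rng.random(20)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert correlate_feature(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_feature(np.ones(10), np.arange(10.0))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_spearman_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(25), rng.random(25)
        base = correlate_feature(x, y)
        assert correlate_feature(np.exp(3 * x), y) == pytest.approx(base, abs=1e-12)
        assert correlate_feature(x, y ** 3) == pytest.approx(base, abs=1e-12)
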