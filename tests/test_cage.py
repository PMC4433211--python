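import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _util import aln_frame, level1_frame, cluster_oracle
from cagemap import cage


class TestMultimapWeights:
    def test_single_candidate_gets_weight_one(self):
        df = aln_frame([(0, "chr1", 100, "+"), (1, "chr1", 5000, "+")])
        w = cage.assign_multimap_weights(df)
        assert np.allclose(w, 1.0)

    def test_weights_proportional_to_unique_neighbourhood(self):
        # candidate A has 3 unique tags within 100 bp, candidate B has 1
        rows = [(0, "chr1", 1000, "+"), (0, "chr1", 9000, "+")]
        rows += [(i, "chr1", 1010 + i, "+") for i in range(1, 4)]  # 3 unique near A
        rows += [(4, "chr1", 9050, "+")]  # 1 unique near B
        df = aln_frame(rows)
        w = cage.assign_multimap_weights(df)
        multi = df["tag_id"] == 0
        got = dict(zip(df.loc[multi, "pos"], w[multi]))
        assert got[1000] == pytest.approx(0.75)
        assert got[9000] == pytest.approx(0.25)

    def test_equal_weight_fallback_when_no_unique_neighbours(self):
        df = aln_frame([(0, "chr1", 1000, "+"), (0, "chr1", 9000, "+")])
        w = cage.assign_multimap_weights(df)
        assert np.allclose(w, 0.5)

    def test_window_is_same_strand(self):
        # unique tags on the opposite strand must not count
        rows = [(0, "chr1", 1000, "+"), (0, "chr1", 9000, "+"),
                (1, "chr1", 1010, "-"), (2, "chr1", 1020, "-")]
        df = aln_frame(rows)
        w = cage.assign_multimap_weights(df)
        assert np.allclose(w[df["tag_id"] == 0], 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_weights_sum_to_one_per_tag(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        tid = 0
        for _ in range(40):
            k = int(rng.integers(1, 5))
            for _ in range(k):
                rows.append((tid, "chr1", int(rng.integers(0, 100_000)), "+-"[rng.integers(2)]))
            tid += 1
        df = aln_frame(rows)
        w = cage.assign_multimap_weights(df)
        sums = pd.Series(w).groupby(df["tag_id"]).sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestLevel1:
    def test_weights_sum_at_same_base(self):
        df = aln_frame([(0, "chr1", 100, "+"), (0, "chr1", 900, "+"),
                        (1, "chr1", 100, "+"), (1, "chr1", 900, "+")])
        lv = cage.build_level1(df, np.array([0.5, 0.5, 0.5, 0.5]))
        assert lv.loc[lv["pos"] == 100, "count"].item() == pytest.approx(1.0)

    def test_opposite_strands_stay_distinct(self):
        df = aln_frame([(0, "chr1", 100, "+"), (1, "chr1", 100, "-")])
        lv = cage.build_level1(df, np.ones(2))
        assert len(lv) == 2
        assert set(lv["strand"]) == {"+", "-"}

    def test_empty_library(self):
        df = aln_frame([]).astype({"tag_id": int, "pos": int})
        lv = cage.build_level1(df, np.zeros(0))
        assert len(lv) == 0

    def test_count_conservation(self, tiny_fixture):
        aln = tiny_fixture.alignments["cond1"]
        w = cage.assign_multimap_weights(aln)
        lv = cage.build_level1(aln, w)
        assert lv["count"].sum() == pytest.approx(aln["tag_id"].nunique(), rel=1e-9)


class TestTpm:
    def test_definition(self):
        lv = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "strand": ["+"],
                           "count_cond1": [10.0], "count_cond2": [5.0]})
        out = cage.normalize_tpm(lv, {"cond1": 1_000_000, "cond2": 500_000})
        assert out["tpm_cond1"].item() == pytest.approx(10.0)
        assert out["tpm_cond2"].item() == pytest.approx(10.0)

    def test_zero_library_raises(self):
        lv = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "strand": ["+"], "count_cond1": [1.0]})
        with pytest.raises(ValueError):
            cage.normalize_tpm(lv, {"cond1": 0})


class TestClustering:
    def test_gap_rule_example(self):
        lv = level1_frame([("chr1", 100, "+", 20, 0), ("chr1", 110, "+", 20, 0),
                           ("chr1", 140, "+", 20, 0)])
        prom, _ = cage.cluster_level2(lv, min_tpm=0.0)
        spans = sorted(zip(prom["start"], prom["end"]))
        assert spans == [(100, 111), (140, 141)]

    def test_boundary_19_merges_20_splits(self):
        for gap, n_expected in ((19, 1), (20, 2)):
            lv = level1_frame([("chr1", 100, "+", 20, 0), ("chr1", 100 + gap, "+", 20, 0)])
            prom, _ = cage.cluster_level2(lv, min_tpm=0.0)
            assert len(prom) == n_expected

    def test_tpm_filter(self):
        # 12 tpm in one condition is kept, 9/9 is discarded
        lv = level1_frame([("chr1", 100, "+", 12, 0), ("chr1", 500, "+", 9, 9)])
        prom, _ = cage.cluster_level2(lv, min_tpm=10.0)
        assert len(prom) == 1 and prom["start"].item() == 100

    def test_unsorted_input_rejected(self):
        lv = level1_frame([("chr1", 100, "+", 1, 0), ("chr1", 50, "+", 1, 0)])
        shuffled = lv.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            cage.cluster_level2(shuffled, min_tpm=0.0)

    def test_promoter_tpm_is_member_sum(self):
        lv = level1_frame([("chr1", 100, "+", 5, 1), ("chr1", 105, "+", 7, 2)])
        prom, members = cage.cluster_level2(lv, min_tpm=0.0)
        assert prom["tpm_cond1"].item() == pytest.approx(12.0)
        assert (members["promoter_id"] == prom["promoter_id"].item()).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 60))
    def test_matches_transitive_closure_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        positions = np.unique(rng.integers(0, 2_000, size=n))
        lv = level1_frame([("chr1", int(p), "+", 1, 0) for p in positions])
        prom, _ = cage.cluster_level2(lv, min_tpm=0.0)
        expected = cluster_oracle(positions)
        # compare cluster boundaries (members are all input positions)
        exp_spans = sorted((g[0], g[-1] + 1) for g in expected)
        assert sorted((s, e) for s, e in zip(prom["start"], prom["end"])) == exp_spans

    def test_monotonicity_in_min_tpm_and_gap(self):
        rng = np.random.default_rng(0)
        lv = level1_frame(
            [("chr1", int(p), "+", float(rng.integers(1, 30)), 0.0)
             for p in np.unique(rng.integers(0, 5_000, size=200))]
        )
        n = {}
        for min_tpm in (0, 5, 10, 50):
            prom, _ = cage.cluster_level2(lv, min_tpm=min_tpm)
            n[min_tpm] = len(prom)
        assert n[0] >= n[5] >= n[10] >= n[50]
        m = {}
        for gap in (5, 20, 100):
            prom, _ = cage.cluster_level2(lv, max_gap=gap, min_tpm=0.0)
            m[gap] = len(prom)
        assert m[5] >= m[20] >= m[100]


class TestDominantTss:
    def test_highest_expression_wins(self):
        assert cage.select_dominant_tss([100, 110], [3.0, 7.0], "+") == 110

    def test_tie_breaks_five_prime(self):
        assert cage.select_dominant_tss([100, 110], [5.0, 5.0], "+") == 100
        assert cage.select_dominant_tss([100, 110], [5.0, 5.0], "-") == 110

    def test_single_member(self):
        assert cage.select_dominant_tss([42], [1.0], "+") == 42

    def test_clustered_dominant_matches_standalone(self):
        lv = level1_frame([("chr1", 100, "+", 3, 1), ("chr1", 105, "+", 2, 9)])
        prom, _ = cage.cluster_level2(lv, min_tpm=0.0)
        # pooled tpm: pos 100 -> 4, pos 105 -> 11
        assert prom["dominant_tss"].item() == 105
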