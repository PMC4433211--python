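import numpy as np
import pandas as pd
import pytest

from _util import level1_frame
from cagemap import integrate
from cagemap.genome import GeneModel, GenomeModel


def _model(genes):
    return GenomeModel({"chr1": 1_000_000}, genes)


class TestMask:
    def test_tss_and_exon_blocks_merge(self):
        # one + strand gene with a 300-bp exon at its start:
        # TSS +/-500 = [9500,10500), exon +/-200 = [9800,10500) -> one block
        g = GeneModel("G", "chr1", "+", ((10_000, 10_300),), "noncoding")
        mask = integrate.build_mask(_model([g]))
        assert len(mask) == 1
        assert (mask["start"].item(), mask["end"].item()) == (9_500, 10_500)

    def test_no_genes_empty_mask(self):
        mask = integrate.build_mask(_model([]))
        assert len(mask) == 0

    def test_nearby_genes_merge_into_one_block(self):
        g1 = GeneModel("G1", "chr1", "+", ((10_000, 10_100),), "noncoding")
        g2 = GeneModel("G2", "chr1", "+", ((10_500, 10_600),), "noncoding")
        mask = integrate.build_mask(_model([g1, g2]))
        assert len(mask) == 1  # 500+500 > 400 bp gap

    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(0)
        genes = []
        pos = 5_000
        for i in range(20):
            pos += int(rng.integers(2_000, 30_000))
            genes.append(GeneModel(f"G{i}", "chr1", "+", ((pos, pos + 500),), "noncoding"))
        mask = integrate.build_mask(_model(genes))
        covered = np.zeros(1_000_000, dtype=bool)
        for g in genes:
            covered[max(0, g.tss - 500): g.tss + 500] = True
            for s, e in g.exons:
                covered[max(0, s - 200): e + 200] = True
        got = np.zeros(1_000_000, dtype=bool)
        for _, r in mask.iterrows():
            got[r["start"]: r["end"]] = True
        assert (got == covered).all()


def _divergent_locus(minus_center, plus_center, n_minus=5, n_plus=5, chrom="chr1"):
    rows = []
    for i in range(n_minus):
        rows.append((chrom, minus_center + i, "-", 1.0, 0.0))
    for i in range(n_plus):
        rows.append((chrom, plus_center + i, "+", 1.0, 0.0))
    return rows


class TestCageEnhancers:
    EMPTY_MASK = pd.DataFrame(columns=["chrom", "start", "end"])

    def test_balanced_divergent_pair_called(self):
        lv = level1_frame(_divergent_locus(10_000, 10_200))
        out = integrate.call_cage_enhancers(lv, self.EMPTY_MASK)
        assert len(out) == 1
        assert out["directionality"].item() == pytest.approx(0.0)
        assert out["total_cond1"].item() == 10

    def test_single_tag_locus_not_called(self):
        lv = level1_frame([("chr1", 10_000, "-", 1.0, 0.0), ("chr1", 10_200, "+", 0.5, 0.0)])
        out = integrate.call_cage_enhancers(lv, self.EMPTY_MASK)
        assert len(out) == 0

    def test_two_pooled_tags_pass_cutoff(self):
        # exactly 2 tags in one sample passes, 1 does not
        lv = level1_frame([("chr1", 10_000, "-", 1.0, 0.0), ("chr1", 10_200, "+", 1.0, 0.0)])
        out = integrate.call_cage_enhancers(lv, self.EMPTY_MASK)
        assert len(out) == 1

    def test_masked_locus_excluded(self):
        lv = level1_frame(_divergent_locus(10_000, 10_200))
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [9_700], "end": [10_300]})
        out = integrate.call_cage_enhancers(lv, mask)
        assert len(out) == 0

    def test_convergent_pair_not_called(self):
        # plus cluster left of minus cluster = convergent, not an eRNA locus
        lv = level1_frame(_divergent_locus(10_200, 10_000))
        out = integrate.call_cage_enhancers(lv, self.EMPTY_MASK)
        assert len(out) == 0

    def test_imbalanced_locus_fails_directionality(self):
        lv = level1_frame(_divergent_locus(10_000, 10_200, n_minus=1, n_plus=30))
        out = integrate.call_cage_enhancers(lv, self.EMPTY_MASK)
        assert len(out) == 0

    def test_window_limit_on_cluster_gap(self):
        called = integrate.call_cage_enhancers(
            level1_frame(_divergent_locus(10_000, 10_395)), self.EMPTY_MASK, window=400
        )
        assert len(called) == 1
        too_far = integrate.call_cage_enhancers(
            level1_frame(_divergent_locus(10_000, 10_500)), self.EMPTY_MASK, window=400
        )
        assert len(too_far) == 0

    def test_matches_exhaustive_pair_oracle(self):
        """Agreement with a brute-force scan of every divergent cluster pair
        on random small loci."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            rows = []
            for pos in np.unique(rng.integers(0, 5_000, size=rng.integers(5, 40))):
                rows.append(("chr1", int(pos), "+-"[rng.integers(2)],
                             float(rng.integers(0, 3)), float(rng.integers(0, 3))))
            lv = level1_frame(rows)
            lv = lv[(lv[["count_cond1", "count_cond2"]].sum(axis=1)) > 0].reset_index(drop=True)
            got = integrate.call_cage_enhancers(lv, self.EMPTY_MASK)
            expected = _enhancer_oracle(lv)
            assert len(got) == len(expected)
            assert sorted(zip(got["start"], got["end"])) == sorted(expected)

    def test_no_call_intersects_mask(self, tiny_fixture, tiny_result):
        enh = tiny_result.cage_enhancers
        mask = tiny_result.mask
        for _, r in enh.iterrows():
            hit = mask[(mask["chrom"] == r["chrom"]) & (mask["start"] < r["end"]) & (mask["end"] > r["start"])]
            assert len(hit) == 0


def _enhancer_oracle(lv, window=400, min_tags=2.0, max_dir=0.8, max_gap=20):
    """Enumerate all divergent cluster pairs, filter, then greedily keep the
    highest-total non-overlapping candidates."""
    from _util import cluster_oracle

    clusters = {}
    for strand in "+-":
        sub = lv[lv["strand"] == strand]
        clusters[strand] = []
        if len(sub) == 0:
            continue
        for grp in cluster_oracle(sub["pos"].tolist(), max_gap=max_gap):
            rows = sub[sub["pos"].isin(grp)]
            clusters[strand].append({
                "start": min(grp), "end": max(grp) + 1,
                "c1": rows["count_cond1"].sum(), "c2": rows["count_cond2"].sum(),
            })
    cands = []
    for m in clusters["-"]:
        for p in clusters["+"]:
            m5, p5 = m["end"] - 1, p["start"]
            if not (0 <= p5 - m5 <= window):
                continue
            t1, t2 = m["c1"] + p["c1"], m["c2"] + p["c2"]
            pooled_plus = p["c1"] + p["c2"]
            pooled_minus = m["c1"] + m["c2"]
            tot = pooled_plus + pooled_minus
            if max(t1, t2) < min_tags or tot == 0:
                continue
            if abs((pooled_plus - pooled_minus) / tot) > max_dir:
                continue
            cands.append((tot, min(m["start"], p["start"]), max(m["end"], p["end"])))
    cands.sort(key=lambda x: -x[0])
    kept = []
    for tot, s, e in cands:
        if not any(s < ke and ks < e for ks, ke in kept):
            kept.append((s, e))
    return kept


class TestOverlapWindow:
    def _prom(self, start, end):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})

    def _reg(self, start, end):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end],
                             "label": ["promoter"]})

    def test_within_window_matched(self):
        res = integrate.overlap_promoters_islands(self._prom(10_000, 10_100), self._reg(11_500, 12_000))
        assert res["promoter_fraction_matched"] == 1.0

    def test_boundary_2000_matched_2001_not(self):
        # promoter's last base 10_099: region base at 12_099 is 2 kb away
        res = integrate.overlap_promoters_islands(self._prom(10_000, 10_100), self._reg(12_099, 12_400))
        assert res["promoter_fraction_matched"] == 1.0
        res = integrate.overlap_promoters_islands(self._prom(10_000, 10_100), self._reg(12_100, 12_400))
        assert res["promoter_fraction_matched"] == 0.0

    def test_empty_region_set(self):
        res = integrate.overlap_promoters_islands(
            self._prom(10_000, 10_100), pd.DataFrame(columns=["chrom", "start", "end", "label"])
        )
        assert res["promoter_fraction_matched"] == 0.0


class TestTranscribedEnhancerTable:
    def _calls(self, gene_id, biotype, c1, c2):
        return pd.DataFrame({
            "promoter_id": ["P0"], "chrom": ["chr1"], "start": [10_050], "end": [10_080],
            "gene_id": [gene_id], "biotype": [biotype],
            "count_cond1": [c1], "count_cond2": [c2],
        })

    def _catalog(self, spec="common"):
        return pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_400],
                             "specificity": [spec]})

    def test_unannotated_inside_common_enhancer_counted_both(self):
        table, sel = integrate.find_transcribed_enhancers(self._calls("", "unassigned", 5, 7), self._catalog())
        assert table.loc["both", "common"] == 1
        assert len(sel) == 1

    def test_coding_promoter_excluded(self):
        table, sel = integrate.find_transcribed_enhancers(self._calls("G1", "coding", 5, 7), self._catalog())
        assert table.to_numpy().sum() == 0

    def test_noncoding_annotated_included(self):
        table, _ = integrate.find_transcribed_enhancers(
            self._calls("G1", "noncoding", 5, 0), self._catalog("cond1_specific")
        )
        assert table.loc["cond1", "cond1_specific"] == 1

    def test_outside_enhancers_excluded(self):
        catalog = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [50_400],
                                "specificity": ["common"]})
        table, _ = integrate.find_transcribed_enhancers(self._calls("", "unassigned", 5, 7), catalog)
        assert table.to_numpy().sum() == 0


class TestDistanceFilter:
    def _reg(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10_000, 50_000],
                             "end": [10_400, 50_400], "label": ["enhancer", "enhancer"]})

    def test_distal_and_proximal(self):
        prom = pd.DataFrame({"chrom": ["chr1"], "start": [10_100], "end": [10_200]})
        out, frac = integrate.enhancer_promoter_distance_filter(self._reg(), prom)
        by_start = out.set_index("start")
        assert by_start.loc[10_000, "promoter_distance"] == 0.0
        assert not by_start.loc[10_000, "distal"]
        assert by_start.loc[50_000, "distal"]
        assert frac == 0.5

    def test_no_promoters_all_distal(self):
        out, frac = integrate.enhancer_promoter_distance_filter(
            self._reg(), pd.DataFrame(columns=["chrom", "start", "end"])
        )
        assert frac == 1.0
        assert np.isinf(out["promoter_distance"]).all()


class TestCorrelation:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10, dtype=float)
        assert integrate.correlate_signal_expression(x, x) == pytest.approx(1.0)
        assert integrate.correlate_signal_expression(x, -x) == pytest.approx(-1.0)

    def test_null_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        y = rng.permutation(x)
        assert abs(integrate.correlate_signal_expression(x, y)) < 0.05

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            r = integrate.correlate_signal_expression(np.ones(5), np.arange(5.0))
        assert np.isnan(r)

    def test_log_transform_flag(self):
        from scipy import stats

        x = np.array([0.0, 9.0, 99.0, 999.0])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        expected = stats.pearsonr(np.log10(x + 1), np.log10(y + 1))[0]
        assert integrate.correlate_signal_expression(x, y, log_transform=True) == pytest.approx(expected)
        # a perfectly log-linear pair reaches r = 1 only after the transform
        assert integrate.correlate_signal_expression(x, x, log_transform=True) == pytest.approx(1.0)
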