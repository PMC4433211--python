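import numpy as np
import pandas as pd
import pytest

from cagemap import annotate
from cagemap.genome import GeneModel, GenomeModel


def ctx(model, pos, strand):
    tss = pd.DataFrame({"chrom": ["chr1"], "pos": [pos], "strand": [strand]})
    out = annotate.classify_tss_context(tss, model)
    return out["context"].item(), out["orientation"].item()


class TestContext:
    def test_promoter_window(self):
        # 300 bp from the annotated + TSS
        assert ctx(_MODEL, 9_700, "+") == ("promoter", "sense")

    def test_intron_sense_beyond_promoter_window(self):
        assert ctx(_MODEL, 11_500, "+") == ("intron", "sense")

    def test_5utr_beats_exon(self):
        # inside first exon, before the CDS, past the 500 bp promoter window
        assert ctx(_MODEL, 10_550, "+") == ("5utr", "sense")

    def test_cds_exon(self):
        assert ctx(_MODEL, 12_500, "+") == ("exon", "sense")

    def test_3utr(self):
        assert ctx(_MODEL, 14_700, "+") == ("3utr", "sense")

    def test_antisense_orientation(self):
        # opposite strand over GA's CDS exon, far from any - strand feature
        assert ctx(_MODEL, 12_500, "-") == ("exon", "antisense")

    def test_noncoding_transcript(self):
        assert ctx(_MODEL, 61_000, "+") == ("noncoding_transcript", "sense")

    def test_intergenic(self):
        assert ctx(_MODEL, 50_000, "+") == ("intergenic", "sense")

    def test_off_chromosome_raises(self):
        with pytest.raises(ValueError):
            ctx(_MODEL, 100_000, "+")

    def test_precedence_matches_enumeration_oracle(self):
        """Label equals the highest-precedence feature among all overlapping
        ones, enumerated by brute force over the gene models."""
        model = _MODEL
        rng = np.random.default_rng(0)
        order = ["promoter", "5utr", "exon", "intron", "3utr", "noncoding_transcript"]
        for pos in rng.integers(0, 100_000, size=300):
            for strand in "+-":
                got_ctx, got_ori = ctx(model, int(pos), strand)
                expected = ("intergenic", "sense")
                for sense in (True, False):
                    feats = _overlapping_features(model, int(pos), strand if sense else ("-" if strand == "+" else "+"))
                    if feats:
                        best = min(feats, key=order.index)
                        expected = (best, "sense" if sense else "antisense")
                        break
                assert (got_ctx, got_ori) == expected, (pos, strand)


def _overlapping_features(model, pos, strand):
    feats = []
    for g in model.genes:
        if g.chrom != "chr1" or g.strand != strand:
            continue
        if abs(pos - g.tss) <= 500:
            feats.append("promoter")
        if g.biotype == "coding":
            for s, e in g.utr5_intervals():
                if s <= pos < e:
                    feats.append("5utr")
            for s, e in g.cds_exon_intervals():
                if s <= pos < e:
                    feats.append("exon")
            for s, e in g.intron_intervals():
                if s <= pos < e:
                    feats.append("intron")
            for s, e in g.utr3_intervals():
                if s <= pos < e:
                    feats.append("3utr")
        elif g.start <= pos < g.end:
            feats.append("noncoding_transcript")
    return feats


_MODEL = GenomeModel(
    {"chr1": 100_000},
    [
        GeneModel("GA", "chr1", "+", ((10_000, 11_000), (12_000, 13_000), (14_000, 15_000)),
                  "coding", cds=(10_600, 14_400)),
        GeneModel("GB", "chr1", "-", ((30_000, 32_000), (38_000, 40_000)),
                  "coding", cds=(30_500, 39_200)),
        GeneModel("GN", "chr1", "+", ((60_000, 62_000),), "noncoding"),
    ],
)


def _promoters(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "dominant_tss",
                                     "tpm_cond1", "tpm_cond2"])
    df.insert(0, "promoter_id", [f"P{i}" for i in range(len(df))])
    df["count_cond1"] = df["tpm_cond1"]
    df["count_cond2"] = df["tpm_cond2"]
    return df


class TestAssignGene:
    def test_within_400_assigned(self):
        # promoter end at 350 bp from GA's TSS (10_000)
        prom = _promoters([("chr1", 9_600, 9_650, "+", 9_600, 20, 20)])
        out = annotate.assign_gene(prom, _MODEL)
        assert out["gene_id"].item() == "GA"
        assert abs(out["gene_distance"].item()) == 351

    def test_at_401_unannotated(self):
        prom = _promoters([("chr1", 9_580, 9_600, "+", 9_580, 20, 20)])
        out = annotate.assign_gene(prom, _MODEL)
        assert out["gene_id"].item() == ""

    def test_boundary_exactly_400(self):
        prom = _promoters([("chr1", 9_590, 9_601, "+", 9_590, 20, 20)])
        # nearest end 9600 (inclusive) -> distance 400
        out = annotate.assign_gene(prom, _MODEL)
        assert out["gene_id"].item() == "GA"

    def test_nearest_gene_wins(self):
        model = GenomeModel(
            {"chr1": 100_000},
            [GeneModel("G1", "chr1", "+", ((10_100, 11_000),), "noncoding"),
             GeneModel("G2", "chr1", "+", ((10_300, 11_300),), "noncoding")],
        )
        prom = _promoters([("chr1", 9_990, 10_001, "+", 9_990, 20, 20)])
        out = annotate.assign_gene(prom, model)
        assert out["gene_id"].item() == "G1"

    def test_strand_must_match(self):
        prom = _promoters([("chr1", 9_900, 10_001, "-", 9_990, 20, 20)])
        out = annotate.assign_gene(prom, _MODEL)
        assert out["gene_id"].item() == ""

    def test_translation_symmetry(self):
        """Shifting the whole genome by a constant leaves assignments unchanged."""
        shift = 7_919
        genes = [GeneModel(g.gene_id, g.chrom, g.strand,
                           tuple((s + shift, e + shift) for s, e in g.exons),
                           g.biotype, None if g.cds is None else (g.cds[0] + shift, g.cds[1] + shift))
                 for g in _MODEL.genes]
        shifted = GenomeModel({"chr1": 200_000}, genes)
        prom = _promoters([("chr1", 9_600, 9_650, "+", 9_600, 20, 20),
                           ("chr1", 9_580, 9_600, "+", 9_580, 20, 20)])
        base = annotate.assign_gene(prom, _MODEL)
        moved = prom.copy()
        moved[["start", "end", "dominant_tss"]] += shift
        out = annotate.assign_gene(moved, shifted)
        assert list(out["gene_id"]) == list(base["gene_id"])


class TestAlternativePromoters:
    def test_counting_and_fraction(self):
        prom = _promoters([
            ("chr1", 9_900, 10_001, "+", 10_000, 10, 10),
            ("chr1", 12_000, 12_010, "+", 12_000, 5, 0),
        ])
        ann = prom.copy()
        ann["gene_id"] = ["GA", "GA"]
        table, frac = annotate.count_alternative_promoters(ann)
        row = table.set_index("gene_id").loc["GA"]
        assert row["n_promoters_cond1"] == 2
        assert row["n_promoters_cond2"] == 1  # second promoter silent in cond2
        assert frac["cond1"] == 1.0

    def test_empty_input(self):
        ann = _promoters([])
        ann["gene_id"] = pd.Series(dtype=object)
        table, frac = annotate.count_alternative_promoters(ann)
        assert len(table) == 0
        assert frac == {"cond1": 0.0, "cond2": 0.0}


class TestTfbsRegions:
    def test_plus_strand_window(self):
        prom = _promoters([("chr1", 9_990, 10_010, "+", 10_000, 20, 20)])
        bed = annotate.export_tfbs_regions(prom, {"chr1": 100_000})
        assert (bed["start"].item(), bed["end"].item()) == (9_700, 10_100)

    def test_minus_strand_mirrored(self):
        prom = _promoters([("chr1", 9_990, 10_010, "-", 10_000, 20, 20)])
        bed = annotate.export_tfbs_regions(prom, {"chr1": 100_000})
        assert (bed["start"].item(), bed["end"].item()) == (9_900, 10_300)

    def test_clipped_at_chromosome_start(self):
        prom = _promoters([("chr1", 40, 60, "+", 50, 20, 20)])
        bed = annotate.export_tfbs_regions(prom, {"chr1": 100_000})
        assert bed["start"].item() == 0
        assert bed["end"].item() == 150


class TestBidirectional:
    def test_divergent_pair_flagged(self):
        prom = _promoters([("chr1", 10_000, 10_010, "+", 10_000, 20, 20),
                           ("chr1", 9_700, 9_710, "-", 9_705, 20, 20),
                           ("chr1", 50_000, 50_010, "+", 50_000, 20, 20)])
        flags = annotate.flag_bidirectional(prom)
        assert list(flags) == [True, True, False]

    def test_partition_every_tss_labelled(self, tiny_fixture, tiny_result):
        calls = tiny_result.calls
        assert calls["context"].isin(annotate.CONTEXTS).all()
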