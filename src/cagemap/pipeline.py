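"""End-to-end orchestration: CAGE promoters -> annotation -> differential ->
chromatin states -> integration, with a summary mirroring the study's
headline tables (promoter counts and classes, context fractions, annotation
rates, epigenetic-state x regulation table, enhancer counts and specificity,
transcribed-enhancer cross-tab, bidirectional CAGE-enhancer calls)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, cage, chromatin, differential, integrate, synthetic
from .config import RunConfig
from .genome import GenomeModel, write_gtf, write_bed12, write_chrom_sizes, read_gtf, read_chrom_sizes
from .synthetic import CONDITIONS, TruthSet

log = logging.getLogger("cagemap")


@dataclass
class Fixture:
    model: GenomeModel
    truth: TruthSet
    alignments: dict  # condition -> alignment DataFrame
    islands: dict  # (mark, condition) -> island DataFrame
    island_totals: dict
    params: dict = field(default_factory=dict)


@dataclass
class AnalysisResult:
    level1: pd.DataFrame
    promoters: pd.DataFrame
    members: pd.DataFrame
    calls: pd.DataFrame  # annotated + differential promoter table
    regions: dict  # condition -> regulatory-region DataFrame
    transitions_table: pd.DataFrame
    poised_to_active: pd.DataFrame
    enhancer_catalog: pd.DataFrame
    cage_enhancers: pd.DataFrame
    table1: pd.DataFrame
    mask: pd.DataFrame
    tfbs_regions: pd.DataFrame
    library_totals: dict
    summary: dict


FIXTURE_SIZES = {
    # (n_chroms, chrom_length, n_genes, n_promoters, class_counts,
    #  n_bivalent, n_enhancers, n_transcribed, depth, noise_rate)
    "tiny": dict(
        n_chroms=1, chrom_length=2_000_000, n_genes=50, n_promoters=20,
        class_counts={"cond1_specific": 2, "cond2_specific": 2, "up": 3, "down": 3, "common": 10},
        n_bivalent=3, n_enhancers=10, n_transcribed=4, depth=50_000, noise_rate=1e-5,
    ),
    "demo": dict(
        n_chroms=3, chrom_length=10_000_000, n_genes=500, n_promoters=200,
        class_counts={"cond1_specific": 20, "cond2_specific": 20, "up": 30, "down": 30, "common": 100},
        n_bivalent=30, n_enhancers=100, n_transcribed=20, depth=1_000_000, noise_rate=1e-5,
    ),
}


def make_fixture(
    size: str = "tiny",
    seed: int = 0,
    outdir=None,
    noise_rate: float | None = None,
    noise_islands: int = 5,
    multimap_frac: float = 0.15,
) -> Fixture:
    """Build a canned synthetic fixture (``tiny`` or ``demo``) and optionally
    write its inputs + truth to ``outdir``."""
    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    p = dict(FIXTURE_SIZES[size])
    if noise_rate is not None:
        p["noise_rate"] = noise_rate
    model = _build_model(p, seed)
    truth = synthetic.plant_truth(
        model, n_promoters=p["n_promoters"], class_counts=p["class_counts"],
        n_bivalent=p["n_bivalent"], n_enhancers=p["n_enhancers"],
        n_transcribed=p["n_transcribed"], seed=seed + 1,
    )
    alignments, truth = synthetic.simulate_cage_libraries(
        model, truth, depth=p["depth"], multimap_frac=multimap_frac,
        noise_rate=p["noise_rate"], seed=seed + 2,
    )
    islands, totals = synthetic.simulate_chip_islands(
        model, truth, noise_islands=noise_islands, seed=seed + 3
    )
    fixture = Fixture(model=model, truth=truth, alignments=alignments,
                      islands=islands, island_totals=totals,
                      params={**p, "seed": seed, "multimap_frac": multimap_frac,
                              "noise_islands": noise_islands})
    if outdir is not None:
        write_fixture(fixture, outdir)
    return fixture


def _build_model(p: dict, seed: int) -> GenomeModel:
    from .genome import build_genome_model

    return build_genome_model(
        n_chroms=p["n_chroms"], n_genes=p["n_genes"], seed=seed,
        chrom_length=p["chrom_length"],
    )


def write_fixture(fixture: Fixture, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(fixture.model, outdir / "genes.gtf")
    write_bed12(fixture.model, outdir / "genes.bed12")
    write_chrom_sizes(fixture.model, outdir / "chrom.sizes")
    for cond, df in fixture.alignments.items():
        synthetic.write_alignments_bed(df, outdir / f"cage_{cond}.bed")
    for (mark, cond), df in fixture.islands.items():
        synthetic.write_islands_bed(df, mark, outdir / f"islands_{mark}_{cond}.bed")
    synthetic.write_truth_json(fixture.truth, outdir / "truth.json")
    (outdir / "island_totals.json").write_text(
        json.dumps({f"{m}:{c}": t for (m, c), t in fixture.island_totals.items()}, indent=1)
    )
    (outdir / "fixture_params.json").write_text(json.dumps(fixture.params, indent=1))


def load_fixture(indir) -> Fixture:
    indir = Path(indir)
    sizes = read_chrom_sizes(indir / "chrom.sizes")
    model = read_gtf(indir / "genes.gtf", sizes)
    truth = synthetic.read_truth_json(indir / "truth.json")
    alignments = {
        cond: synthetic.read_alignments_bed(indir / f"cage_{cond}.bed") for cond in CONDITIONS
    }
    islands, totals = {}, {}
    totals_doc = json.loads((indir / "island_totals.json").read_text())
    for key, t in totals_doc.items():
        mark, cond = key.split(":")
        islands[(mark, cond)] = synthetic.read_islands_bed(indir / f"islands_{mark}_{cond}.bed")
        totals[(mark, cond)] = t
    params = json.loads((indir / "fixture_params.json").read_text())
    return Fixture(model=model, truth=truth, alignments=alignments,
                   islands=islands, island_totals=totals, params=params)


# ---------------------------------------------------------------------------
# the analysis proper


def run_analysis(
    alignments: dict,
    islands: dict,
    island_totals: dict,
    model: GenomeModel,
    cfg: RunConfig | None = None,
) -> AnalysisResult:
    """Run every stage on in-memory inputs and assemble the summary."""
    cfg = cfg or RunConfig()
    cfg.validate()

    # --- CAGE core
    log.info("stage cage: weighting multimapped tags and building Level-1 TSSs")
    level1_by_cond = {}
    library_totals = {}
    for cond in CONDITIONS:
        aln = alignments[cond]
        w = cage.assign_multimap_weights(aln, window=cfg.weight_window)
        level1_by_cond[cond] = cage.build_level1(aln, w)
        library_totals[cond] = float(aln["tag_id"].nunique())
    level1 = cage.merge_level1_conditions(level1_by_cond)
    level1 = cage.normalize_tpm(level1, library_totals)
    promoters, members = cage.cluster_level2(level1, max_gap=cfg.max_gap, min_tpm=cfg.min_tpm)
    log.info("stage cage: %d Level-1 TSSs, %d promoters", len(level1), len(promoters))

    # --- annotation
    annotated = annotate.annotate_promoters(promoters, model, max_dist=cfg.gene_dist)
    tfbs = annotate.export_tfbs_regions(
        annotated, model.chrom_sizes, upstream=cfg.tfbs_upstream, downstream=cfg.tfbs_downstream
    )
    alt_table, alt_frac = annotate.count_alternative_promoters(annotated)

    # --- differential promoters
    calls = differential.classify_regulation(
        annotated, library_totals, fc_threshold_log2=cfg.fc_log2,
        alpha=cfg.alpha_promoter, min_tpm=cfg.min_tpm,
    )

    # --- chromatin
    regions = {}
    for cond in CONDITIONS:
        reg = chromatin.classify_regions(
            islands[("H3K4me3", cond)], islands[("H3K4me1", cond)],
            island_totals[("H3K4me3", cond)], island_totals[("H3K4me1", cond)],
        )
        regions[cond] = chromatin.call_bivalent(reg, islands[("H3K27me3", cond)])
    calls, trans_table, poised_to_active = chromatin.classify_transitions(
        calls, regions[CONDITIONS[0]], window=cfg.transition_window
    )

    # --- integration
    mask = integrate.build_mask(
        model, tss_halfwidth=cfg.mask_tss_halfwidth, exon_pad=cfg.mask_exon_pad
    )
    cage_enh = integrate.call_cage_enhancers(
        level1, mask, window=cfg.enhancer_window, min_tags=cfg.enhancer_min_tags,
        max_abs_directionality=cfg.enhancer_max_directionality, max_gap=cfg.max_gap,
    )
    cage_enh = differential.call_differential_enhancers(
        cage_enh, library_totals, alpha=cfg.alpha_enhancer,
        fc_min=cfg.fc_enhancer, dispersion=cfg.dispersion,
    )
    catalog = chromatin.enhancer_specificity(regions[CONDITIONS[0]], regions[CONDITIONS[1]])
    table1, _ = integrate.find_transcribed_enhancers(calls, catalog)
    overlap = {
        cond: integrate.overlap_promoters_islands(calls, regions[cond], window=cfg.overlap_window)
        for cond in CONDITIONS
    }
    distal = {
        cond: integrate.enhancer_promoter_distance_filter(
            regions[cond], calls, min_dist=cfg.distal_min_dist
        )[1]
        for cond in CONDITIONS
    }

    summary = _summarize(
        calls, regions, trans_table, poised_to_active, catalog, cage_enh, table1,
        overlap, distal, alt_frac, library_totals, cfg,
    )
    return AnalysisResult(
        level1=level1, promoters=promoters, members=members, calls=calls,
        regions=regions, transitions_table=trans_table, poised_to_active=poised_to_active,
        enhancer_catalog=catalog, cage_enhancers=cage_enh, table1=table1, mask=mask,
        tfbs_regions=tfbs, library_totals=library_totals, summary=summary,
    )


def _summarize(calls, regions, trans_table, poised_to_active, catalog, cage_enh,
               table1, overlap, distal, alt_frac, library_totals, cfg) -> dict:
    n = len(calls)
    expressed = {
        cond: int((calls[f"count_{cond}"] > 0).sum()) for cond in CONDITIONS
    }
    reg_counts = calls["regulation"].value_counts().to_dict()
    context = (calls["context"].value_counts() / n).to_dict() if n else {}
    annotated_frac = float((calls["gene_id"] != "").mean()) if n else 0.0
    by_class_annot = {
        k: float((grp["gene_id"] != "").mean())
        for k, grp in calls.groupby("regulation", observed=True)
    }
    enh_spec = catalog["specificity"].value_counts().to_dict() if len(catalog) else {}
    return {
        "thresholds": cfg.thresholds(),
        "library_totals": {c: library_totals[c] for c in CONDITIONS},
        "n_promoters": n,
        "n_expressed": expressed,
        "regulation_counts": {k: int(reg_counts.get(k, 0)) for k in differential.REGULATION_CLASSES},
        "context_fractions": {k: float(v) for k, v in context.items()},
        "annotated_fraction": annotated_frac,
        "annotated_fraction_by_class": by_class_annot,
        "alternative_promoter_fraction": alt_frac,
        "n_regions": {c: int(len(regions[c])) for c in CONDITIONS},
        "n_promoter_regions": {
            c: int((regions[c]["label"] == "promoter").sum()) for c in CONDITIONS
        },
        "n_enhancer_regions": {
            c: int((regions[c]["label"] == "enhancer").sum()) for c in CONDITIONS
        },
        "n_bivalent_regions": {c: int(regions[c]["bivalent"].sum()) for c in CONDITIONS},
        "transitions": {s: {k: int(v) for k, v in row.items()} for s, row in trans_table.iterrows()},
        "n_poised_to_active": int(len(poised_to_active)),
        "enhancer_specificity_counts": {k: int(v) for k, v in enh_spec.items()},
        "promoter_region_overlap": overlap,
        "enhancer_distal_fraction": distal,
        "table1": {a: {k: int(v) for k, v in row.items()} for a, row in table1.iterrows()},
        "n_cage_enhancers": int(len(cage_enh)),
        "cage_enhancer_calls": cage_enh["call"].value_counts().to_dict() if len(cage_enh) else {},
    }


def write_outputs(result: AnalysisResult, outdir, cfg: RunConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = (cfg or RunConfig()).thresholds()
    for cond in CONDITIONS:
        cage.write_ctss_bed(result.level1, cond, outdir / f"ctss_{cond}.bed")
    cage.write_level1_tsv(result.level1, outdir / "level1.tsv")
    cage.write_promoters(result.promoters, outdir / "promoters.tsv", outdir / "promoters.bed", thresholds)
    _tsv(result.calls, outdir / "promoter_calls.tsv", thresholds)
    for cond in CONDITIONS:
        _tsv(result.regions[cond], outdir / f"regions_{cond}.tsv", thresholds)
        _regions_bed9(result.regions[cond], outdir / f"regions_{cond}.bed")
    _tsv(result.transitions_table.rename_axis("state").reset_index(), outdir / "transitions.tsv", thresholds)
    _tsv(result.poised_to_active, outdir / "poised_to_active.tsv", thresholds)
    _tsv(result.enhancer_catalog, outdir / "enhancer_catalog.tsv", thresholds)
    _tsv(result.cage_enhancers, outdir / "cage_enhancers.tsv", thresholds)
    if len(result.cage_enhancers):
        bed = result.cage_enhancers
        pd.DataFrame({
            "chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
            "name": bed["enhancer_id"],
            "score": np.round(bed["pooled_total"]).astype(int), "strand": ".",
        }).to_csv(outdir / "cage_enhancers.bed", sep="\t", header=False, index=False)
    _tsv(result.table1.rename_axis("activity").reset_index(), outdir / "table1.tsv", thresholds)
    result.mask.to_csv(outdir / "mask.bed", sep="\t", header=False, index=False)
    result.tfbs_regions.to_csv(outdir / "tfbs_regions.bed", sep="\t", header=False, index=False)
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=1, sort_keys=True))


def _tsv(df: pd.DataFrame, path, thresholds: dict) -> None:
    with open(path, "w") as fh:
        for k, v in thresholds.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


_REGION_COLORS = {("promoter", False): "255,0,0", ("promoter", True): "128,128,128",
                  ("enhancer", False): "0,128,0", ("enhancer", True): "0,128,0"}


def _regions_bed9(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            color = _REGION_COLORS[(r["label"], bool(r["bivalent"]))]
            name = r["label"] + ("_bivalent" if r["bivalent"] else "")
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\t0\t.\t"
                f"{r['start']}\t{r['end']}\t{color}\n"
            )


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    """File-based end-to-end run: load the inputs named in the config, run the
    analysis and write every artifact plus ``summary.json`` to the outdir."""
    cfg.validate()
    for cond in CONDITIONS:
        if cond not in cfg.alignments:
            raise FileNotFoundError(f"missing alignments for {cond}")
    for path in list(cfg.alignments.values()) + list(cfg.islands.values()):
        if not Path(path).exists():
            raise FileNotFoundError(str(path))
    if cfg.annotation_gtf is None or cfg.chrom_sizes is None:
        raise FileNotFoundError("annotation_gtf and chrom_sizes are required")
    model = read_gtf(cfg.annotation_gtf, read_chrom_sizes(cfg.chrom_sizes))
    alignments = {c: synthetic.read_alignments_bed(cfg.alignments[c]) for c in CONDITIONS}
    islands, totals = {}, {}
    for key, path in cfg.islands.items():
        mark, cond = key.split(":")
        islands[(mark, cond)] = synthetic.read_islands_bed(path)
        totals[(mark, cond)] = max(int(islands[(mark, cond)]["count"].sum()), 1)
    result = run_analysis(alignments, islands, totals, model, cfg)
    write_outputs(result, cfg.outdir, cfg)
    return result


def run_fixture(fixture: Fixture, cfg: RunConfig | None = None) -> AnalysisResult:
    """Run the analysis directly on an in-memory fixture."""
    return run_analysis(
        fixture.alignments, fixture.islands, fixture.island_totals, fixture.model, cfg
    )
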