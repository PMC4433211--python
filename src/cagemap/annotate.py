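"""Genomic context, gene assignment and motif-region export for CAGE promoters.

A TSS is placed in exactly one context category using a fixed precedence over
same-strand features — promoter window (annotated TSS +/- 500 bp) > 5' UTR >
exon > intron > 3' UTR > noncoding transcript — falling back to the same
precedence on the opposite strand (reported with antisense orientation) and
finally to intergenic.  Promoters are assigned to the nearest same-strand
gene whose annotated TSS lies within 400 bp of either promoter end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .synthetic import CONDITIONS

CONTEXTS = ("promoter", "5utr", "exon", "intron", "3utr", "noncoding_transcript", "intergenic")

_PRECEDENCE = ("promoter", "5utr", "exon", "intron", "3utr", "noncoding_transcript")


class FeatureIndex:
    """Per-(chrom, strand) sorted feature intervals for context lookup."""

    def __init__(self, model: GenomeModel, promoter_halfwidth: int = 500):
        self.model = model
        self.promoter_halfwidth = promoter_halfwidth
        feats = {}  # (chrom, strand, kind) -> list of (start, end)
        for g in model.genes:
            h = promoter_halfwidth
            _add(feats, g.chrom, g.strand, "promoter", max(0, g.tss - h), g.tss + h + 1)
            if g.biotype == "coding":
                for s, e in g.utr5_intervals():
                    _add(feats, g.chrom, g.strand, "5utr", s, e)
                for s, e in g.cds_exon_intervals():
                    _add(feats, g.chrom, g.strand, "exon", s, e)
                for s, e in g.intron_intervals():
                    _add(feats, g.chrom, g.strand, "intron", s, e)
                for s, e in g.utr3_intervals():
                    _add(feats, g.chrom, g.strand, "3utr", s, e)
            else:
                _add(feats, g.chrom, g.strand, "noncoding_transcript", g.start, g.end)
        self._sorted = {
            key: (np.array([s for s, _ in iv], dtype=np.int64), np.array([e for _, e in iv], dtype=np.int64))
            for key, iv in ((k, sorted(v)) for k, v in feats.items())
        }

    def hits(self, chrom: str, strand: str, kind: str, pos: np.ndarray) -> np.ndarray:
        key = (chrom, strand, kind)
        if key not in self._sorted:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = self._sorted[key]
        # intervals may overlap between genes; sweep with running max end
        run_end = np.maximum.accumulate(ends)
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, starts.size - 1)
        return (idx >= 0) & (run_end[idx_c] > pos)


def _add(feats, chrom, strand, kind, s, e):
    if s < e:
        feats.setdefault((chrom, strand, kind), []).append((int(s), int(e)))


def classify_tss_context(
    tss: pd.DataFrame,
    model: GenomeModel,
    index: FeatureIndex | None = None,
) -> pd.DataFrame:
    """Context and orientation for each TSS (columns ``chrom, pos, strand``).

    Returns a DataFrame aligned with the input with ``context`` and
    ``orientation`` columns.  Raises for positions outside the chromosome.
    """
    if index is None:
        index = FeatureIndex(model)
    tss = tss.reset_index(drop=True)
    pos_all = tss["pos"].to_numpy(dtype=np.int64)
    for chrom, grp in tss.groupby("chrom", observed=True):
        size = model.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        p = grp["pos"].to_numpy()
        if (p < 0).any() or (p >= size).any():
            raise ValueError(f"TSS position outside {chrom}")
    context = np.full(len(tss), "intergenic", dtype=object)
    orientation = np.full(len(tss), "sense", dtype=object)
    other = {"+": "-", "-": "+"}
    for (chrom, strand), grp in tss.groupby(["chrom", "strand"], observed=True):
        rows = grp.index.to_numpy()
        p = pos_all[rows]
        unresolved = np.ones(len(rows), dtype=bool)
        for sense, strd in ((True, strand), (False, other[strand])):
            for kind in _PRECEDENCE:
                if not unresolved.any():
                    break
                hit = index.hits(chrom, strd, kind, p) & unresolved
                if hit.any():
                    context[rows[hit]] = kind
                    orientation[rows[hit]] = "sense" if sense else "antisense"
                    unresolved &= ~hit
    out = tss.copy()
    out["context"] = context
    out["orientation"] = orientation
    return out


def flag_bidirectional(promoters: pd.DataFrame, max_dist: int = 500) -> np.ndarray:
    """Divergent-pair flag: an opposite-strand promoter's dominant TSS lies
    within ``max_dist`` bp upstream (tail-to-tail) of this promoter's
    dominant TSS."""
    promoters = promoters.reset_index(drop=True)
    flags = np.zeros(len(promoters), dtype=bool)
    dom = promoters["dominant_tss"].to_numpy(dtype=np.int64)
    strand = promoters["strand"].to_numpy()
    for chrom, grp in promoters.groupby("chrom", observed=True):
        idx = grp.index.to_numpy()
        d = dom[idx]
        s = strand[idx]
        plus = idx[s == "+"]
        minus = idx[s == "-"]
        if plus.size == 0 or minus.size == 0:
            continue
        p_pos = dom[plus]
        m_pos = np.sort(dom[minus])
        # + promoter: divergent partner is a - TSS at lower coordinate within max_dist
        lo = np.searchsorted(m_pos, p_pos - max_dist, side="left")
        hi = np.searchsorted(m_pos, p_pos + 1, side="left")
        flags[plus] = hi > lo
        p_sorted = np.sort(p_pos)
        m_all = dom[minus]
        lo = np.searchsorted(p_sorted, m_all, side="left")
        hi = np.searchsorted(p_sorted, m_all + max_dist + 1, side="left")
        flags[minus] = hi > lo
    return flags


def assign_gene(
    promoters: pd.DataFrame,
    model: GenomeModel,
    max_dist: int = 400,
) -> pd.DataFrame:
    """Nearest same-strand gene whose TSS is within ``max_dist`` bp of either
    promoter end (distance 0 when the gene TSS falls inside the promoter).

    Adds ``gene_id`` (empty string = unannotated), ``gene_distance`` (signed;
    negative = gene TSS upstream of the promoter interval) and ``biotype``.
    """
    promoters = promoters.reset_index(drop=True)
    gene_id = np.full(len(promoters), "", dtype=object)
    gene_distance = np.full(len(promoters), np.nan)
    biotype = np.full(len(promoters), "unassigned", dtype=object)
    by_key = {}
    for g in model.genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    start = promoters["start"].to_numpy(dtype=np.int64)
    end = promoters["end"].to_numpy(dtype=np.int64)
    for (chrom, strand), grp in promoters.groupby(["chrom", "strand"], observed=True):
        genes = by_key.get((chrom, strand))
        if not genes:
            continue
        tss = np.array([g.tss for g in genes], dtype=np.int64)
        order = np.argsort(tss, kind="stable")
        tss_sorted = tss[order]
        idx = grp.index.to_numpy()
        s, e = start[idx], end[idx] - 1  # inclusive ends of the promoter
        # candidate gene TSSs: nearest at/below start, nearest at/above end, and any inside
        cand = np.searchsorted(tss_sorted, s)
        best_d = np.full(idx.size, np.inf)
        best_g = np.full(idx.size, -1)
        for off in (-1, 0, 1):
            j = np.clip(cand + off, 0, tss_sorted.size - 1)
            t = tss_sorted[j]
            inside = (t >= s) & (t <= e)
            d = np.where(inside, 0, np.minimum(np.abs(t - s), np.abs(t - e)))
            better = d < best_d
            best_d = np.where(better, d, best_d)
            best_g = np.where(better, j, best_g)
        # also check candidates near the promoter end
        cand_e = np.searchsorted(tss_sorted, e)
        for off in (-1, 0, 1):
            j = np.clip(cand_e + off, 0, tss_sorted.size - 1)
            t = tss_sorted[j]
            inside = (t >= s) & (t <= e)
            d = np.where(inside, 0, np.minimum(np.abs(t - s), np.abs(t - e)))
            better = d < best_d
            best_d = np.where(better, d, best_d)
            best_g = np.where(better, j, best_g)
        ok = best_d <= max_dist
        for ii in np.flatnonzero(ok):
            g = genes[order[best_g[ii]]]
            gene_id[idx[ii]] = g.gene_id
            t = g.tss
            signed = 0 if s[ii] <= t <= e[ii] else (t - e[ii] if t > e[ii] else t - s[ii])
            gene_distance[idx[ii]] = signed if strand == "+" else -signed
            biotype[idx[ii]] = g.biotype
    out = promoters.copy()
    out["gene_id"] = gene_id
    out["gene_distance"] = gene_distance
    out["biotype"] = biotype
    return out


def annotate_promoters(promoters: pd.DataFrame, model: GenomeModel, max_dist: int = 400) -> pd.DataFrame:
    """Full annotation: TSS context, orientation, bidirectional flag, gene
    assignment and biotype for a Level-2 promoter table."""
    tss = pd.DataFrame(
        {"chrom": promoters["chrom"], "pos": promoters["dominant_tss"], "strand": promoters["strand"]}
    )
    ctx = classify_tss_context(tss.reset_index(drop=True), model)
    out = promoters.reset_index(drop=True).copy()
    out["context"] = ctx["context"].to_numpy()
    out["orientation"] = ctx["orientation"].to_numpy()
    out["bidirectional"] = flag_bidirectional(out)
    out = assign_gene(out, model, max_dist=max_dist)
    return out


def count_alternative_promoters(annotated: pd.DataFrame) -> tuple:
    """Distinct promoters per assigned gene per condition.

    A promoter counts in a condition iff its tpm is > 0 there.  Returns
    ``(table, fraction_multi)`` where ``table`` has one row per gene with
    per-condition promoter counts and ``fraction_multi`` maps condition to the
    fraction of (expressed) genes using >= 2 alternative promoters.
    """
    assigned = annotated[annotated["gene_id"] != ""]
    if len(assigned) == 0:
        empty = pd.DataFrame(columns=["gene_id"] + [f"n_promoters_{c}" for c in CONDITIONS])
        return empty, {c: 0.0 for c in CONDITIONS}
    rows = {}
    for cond in CONDITIONS:
        expressed = assigned[assigned[f"tpm_{cond}"] > 0]
        rows[f"n_promoters_{cond}"] = expressed.groupby("gene_id").size()
    table = pd.DataFrame(rows).fillna(0).astype(int).rename_axis("gene_id").reset_index()
    frac = {}
    for cond in CONDITIONS:
        col = table[f"n_promoters_{cond}"]
        n_genes = int((col > 0).sum())
        frac[cond] = float((col >= 2).sum() / n_genes) if n_genes else 0.0
    return table, frac


def export_tfbs_regions(
    promoters: pd.DataFrame,
    chrom_sizes: dict,
    upstream: int = 300,
    downstream: int = 100,
) -> pd.DataFrame:
    """Strand-aware motif-analysis windows around each dominant TSS:
    ``[TSS - upstream, TSS + downstream]`` on +, mirrored on -, clipped to the
    chromosome."""
    tss = promoters["dominant_tss"].to_numpy(dtype=np.int64)
    plus = promoters["strand"].to_numpy() == "+"
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    sizes = promoters["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    start = np.clip(start, 0, sizes)
    end = np.clip(end, 0, sizes)
    return pd.DataFrame(
        {
            "chrom": promoters["chrom"],
            "start": start,
            "end": end,
            "name": promoters["promoter_id"],
            "score": 0,
            "strand": promoters["strand"],
        }
    )
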