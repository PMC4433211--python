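"""Joining CAGE transcription with epigenetic regions.

* mask construction (annotated TSSs +/- 500 bp, exons +/- 200 bp),
* bidirectional (divergent) CAGE-enhancer calling on the pooled libraries,
* promoter/region +/- 2 kb overlap rates,
* the transcribed-enhancer cross-tabulation (promoter activity x enhancer
  condition-specificity),
* distal-enhancer flagging and signal/expression correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import merge_intervals, nearest_distance, overlaps_any
from .cage import cluster_ids
from .genome import GenomeModel
from .synthetic import CONDITIONS


def build_mask(model: GenomeModel, tss_halfwidth: int = 500, exon_pad: int = 200) -> pd.DataFrame:
    """Union of annotated-TSS +/- ``tss_halfwidth`` and exon +/- ``exon_pad``
    intervals, merged per chromosome (columns ``chrom, start, end``)."""
    rows = []
    for chrom, size in model.chrom_sizes.items():
        starts, ends = [], []
        for g in model.genes:
            if g.chrom != chrom:
                continue
            starts.append(g.tss - tss_halfwidth)
            ends.append(g.tss + tss_halfwidth)
            for s, e in g.exons:
                starts.append(s - exon_pad)
                ends.append(e + exon_pad)
        if not starts:
            continue
        ms, me = merge_intervals(
            np.clip(np.array(starts, dtype=np.int64), 0, size),
            np.clip(np.array(ends, dtype=np.int64), 0, size),
        )
        rows.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def call_cage_enhancers(
    level1: pd.DataFrame,
    mask: pd.DataFrame,
    window: int = 400,
    min_tags: float = 2.0,
    max_abs_directionality: float = 0.8,
    max_gap: int = 20,
) -> pd.DataFrame:
    """Divergent low-level transcription loci from the pooled Level-1 signal.

    Tag clusters are built per strand with the Level-2 chaining rule (< 20 bp,
    no tpm filter) on the pooled counts.  A candidate locus pairs a
    minus-strand cluster whose 5' end (its rightmost base) lies at most
    ``window`` bp left of a plus-strand cluster's 5' end (its leftmost base).
    Loci are kept when the summed tag count of the pair reaches ``min_tags``
    in at least one condition, the pooled directionality score
    ``(plus - minus) / (plus + minus)`` is within ``max_abs_directionality``,
    and the locus interval does not intersect the mask; overlapping candidates
    are merged keeping the highest pooled total.
    """
    count_cols = [f"count_{c}" for c in CONDITIONS if f"count_{c}" in level1.columns]
    lv = level1.sort_values(["chrom", "strand", "pos"], kind="stable", ignore_index=True)
    lv["_pooled"] = lv[count_cols].sum(axis=1)
    lv["_cluster"] = cluster_ids(lv, max_gap=max_gap)

    summit = lv.loc[lv.groupby("_cluster")["_pooled"].idxmax()]
    agg = lv.groupby("_cluster", sort=True).agg(
        chrom=("chrom", "first"),
        strand=("strand", "first"),
        start=("pos", "min"),
        end=("pos", "max"),
        pooled=("_pooled", "sum"),
        **{c: (c, "sum") for c in count_cols},
    )
    agg["end"] = agg["end"] + 1
    agg["summit"] = summit.set_index("_cluster")["pos"]

    mask_by_chrom = {
        chrom: merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in mask.groupby("chrom", observed=True)
    }

    cands = []
    for chrom, grp in agg.groupby("chrom", sort=True, observed=True):
        minus = grp[grp["strand"] == "-"]
        plus = grp[grp["strand"] == "+"]
        if len(minus) == 0 or len(plus) == 0:
            continue
        m5 = (minus["end"].to_numpy() - 1)  # 5' end of a minus cluster = rightmost base
        p5 = plus["start"].to_numpy()
        m_order = np.argsort(m5, kind="stable")
        m5s = m5[m_order]
        for pi in range(len(plus)):
            lo = np.searchsorted(m5s, p5[pi] - window, side="left")
            hi = np.searchsorted(m5s, p5[pi], side="right")
            for mi in m_order[lo:hi]:
                if m5[mi] > p5[pi]:
                    continue
                mrow = minus.iloc[mi]
                prow = plus.iloc[pi]
                cands.append((chrom, mrow, prow))

    rows = []
    for chrom, mrow, prow in cands:
        start = int(min(mrow["start"], prow["start"]))
        end = int(max(mrow["end"], prow["end"]))
        rec = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "midpoint": int((mrow["summit"] + prow["summit"]) // 2),
        }
        pooled_plus = float(prow["pooled"])
        pooled_minus = float(mrow["pooled"])
        for c in CONDITIONS:
            col = f"count_{c}"
            rec[f"plus_{c}"] = float(prow.get(col, 0.0))
            rec[f"minus_{c}"] = float(mrow.get(col, 0.0))
            rec[f"total_{c}"] = rec[f"plus_{c}"] + rec[f"minus_{c}"]
        tot = pooled_plus + pooled_minus
        rec["directionality"] = (pooled_plus - pooled_minus) / tot if tot > 0 else 0.0
        rec["pooled_total"] = tot
        rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return _empty_enhancer_frame()
    keep = df[[f"total_{c}" for c in CONDITIONS]].max(axis=1) >= min_tags
    keep &= df["directionality"].abs() <= max_abs_directionality
    masked = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", observed=True):
        mm = mask_by_chrom.get(chrom)
        if mm is None:
            continue
        masked[grp.index.to_numpy()] = overlaps_any(
            grp["start"].to_numpy(), grp["end"].to_numpy(), mm[0], mm[1]
        )
    df = df[keep.to_numpy() & ~masked].reset_index(drop=True)
    if len(df) == 0:
        return _empty_enhancer_frame()
    # merge overlapping candidates, highest pooled total wins
    df = df.sort_values("pooled_total", ascending=False, kind="stable").reset_index(drop=True)
    kept_rows = []
    kept_by_chrom: dict = {}
    for i in range(len(df)):
        chrom = df.at[i, "chrom"]
        s, e = df.at[i, "start"], df.at[i, "end"]
        clash = any(s < ke and ks < e for ks, ke in kept_by_chrom.get(chrom, ()))
        if not clash:
            kept_by_chrom.setdefault(chrom, []).append((s, e))
            kept_rows.append(i)
    out = df.loc[kept_rows].sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    out.insert(0, "enhancer_id", [f"E{i:05d}" for i in range(len(out))])
    return out


def _empty_enhancer_frame() -> pd.DataFrame:
    cols = ["enhancer_id", "chrom", "start", "end", "midpoint"]
    for c in CONDITIONS:
        cols += [f"plus_{c}", f"minus_{c}", f"total_{c}"]
    cols += ["directionality", "pooled_total"]
    return pd.DataFrame(columns=cols)


def overlap_promoters_islands(
    promoters: pd.DataFrame,
    regions: pd.DataFrame,
    window: int = 2_000,
    label: str = "promoter",
) -> dict:
    """Two-way +/- ``window`` bp overlap rates between CAGE promoters and
    (by default promoter-labelled) regulatory regions."""
    reg = regions[regions["label"] == label] if "label" in regions.columns else regions
    n_prom = len(promoters)
    n_reg = len(reg)
    prom_hit = np.zeros(n_prom, dtype=bool)
    reg_hit = np.zeros(n_reg, dtype=bool)
    reg = reg.reset_index(drop=True)
    promoters = promoters.reset_index(drop=True)
    for chrom, grp in promoters.groupby("chrom", observed=True):
        sub = reg[reg["chrom"] == chrom]
        if len(sub):
            ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            prom_hit[grp.index.to_numpy()] = overlaps_any(
                grp["start"].to_numpy() - window, grp["end"].to_numpy() + window, ms, me
            )
    for chrom, grp in reg.groupby("chrom", observed=True):
        sub = promoters[promoters["chrom"] == chrom]
        if len(sub):
            ms, me = merge_intervals(sub["start"].to_numpy() - window, sub["end"].to_numpy() + window)
            reg_hit[grp.index.to_numpy()] = overlaps_any(
                grp["start"].to_numpy(), grp["end"].to_numpy(), ms, me
            )
    return {
        "promoter_fraction_matched": float(prom_hit.mean()) if n_prom else 0.0,
        "region_fraction_matched": float(reg_hit.mean()) if n_reg else 0.0,
        "n_promoters_matched": int(prom_hit.sum()),
        "n_regions_matched": int(reg_hit.sum()),
    }


def find_transcribed_enhancers(
    annotated_calls: pd.DataFrame,
    enhancer_catalog: pd.DataFrame,
) -> tuple:
    """Cross-tabulate eRNA-like CAGE promoters against enhancer regions.

    Selects CAGE promoters that are unannotated or annotated to non-coding
    biotypes and whose interval lies inside an enhancer region; rows are the
    promoter activity pattern (cond1 only / cond2 only / both, by the
    zero-count rule), columns the enhancer specificity.  Returns
    ``(table, selected)``.
    """
    elig = annotated_calls[
        (annotated_calls["gene_id"] == "") | (annotated_calls["biotype"] == "noncoding")
    ].reset_index(drop=True)
    spec_labels = ["cond1_specific", "cond2_specific", "common"]
    table = pd.DataFrame(0, index=["cond1", "cond2", "both"], columns=spec_labels)
    if len(elig) == 0 or len(enhancer_catalog) == 0:
        return table, elig.iloc[0:0]
    spec = np.full(len(elig), "", dtype=object)
    for chrom, grp in elig.groupby("chrom", observed=True):
        cat = enhancer_catalog[enhancer_catalog["chrom"] == chrom]
        for spec_label in spec_labels:
            sub = cat[cat["specificity"] == spec_label]
            if len(sub) == 0:
                continue
            ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            # promoter interval fully inside an enhancer region
            idx = grp.index.to_numpy()
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            j = np.searchsorted(ms, s, side="right") - 1
            jc = np.clip(j, 0, ms.size - 1)
            inside = (j >= 0) & (me[jc] >= e)
            newly = inside & (spec[idx] == "")
            spec[idx[newly]] = spec_label
    c1 = elig[f"count_{CONDITIONS[0]}"].to_numpy() > 0
    c2 = elig[f"count_{CONDITIONS[1]}"].to_numpy() > 0
    activity = np.where(c1 & c2, "both", np.where(c1, "cond1", np.where(c2, "cond2", "none")))
    sel = spec != ""
    for a, s_ in zip(activity[sel], spec[sel]):
        if a != "none":
            table.loc[a, s_] += 1
    selected = elig[sel].copy()
    selected["enhancer_specificity"] = spec[sel]
    selected["activity"] = activity[sel]
    return table, selected


def enhancer_promoter_distance_filter(
    regions: pd.DataFrame,
    promoters: pd.DataFrame,
    min_dist: int = 2_000,
) -> tuple:
    """Flag enhancer regions as distal (> ``min_dist`` bp from the nearest
    CAGE promoter edge) or promoter-proximal.  Returns ``(flags, distal_fraction)``."""
    enh = regions[regions["label"] == "enhancer"] if "label" in regions.columns else regions
    enh = enh.reset_index(drop=True)
    dist = np.full(len(enh), np.inf)
    for chrom, grp in enh.groupby("chrom", observed=True):
        sub = promoters[promoters["chrom"] == chrom]
        if len(sub) == 0:
            continue
        ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        dist[grp.index.to_numpy()] = nearest_distance(
            grp["start"].to_numpy(), grp["end"].to_numpy(), ms, me
        )
    distal = dist > min_dist
    frac = float(distal.mean()) if len(enh) else 1.0
    out = enh.copy()
    out["promoter_distance"] = dist
    out["distal"] = distal
    return out, frac


def correlate_signal_expression(x, y, log_transform: bool = False) -> float:
    """Pearson correlation between a per-feature signal vector and tpm vector;
    optionally on log10(v + 1) scales.  Returns NaN (with a warning) when
    either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if log_transform:
        x = np.log10(x + 1)
        y = np.log10(y + 1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance input; correlation undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)
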