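"""Histone-mark island classification into promoter/enhancer regions.

Regions bearing H3K4me3 only are promoters, regions bearing H3K4me1 only are
enhancers; when islands of the two marks overlap (transitive, >= 1 bp) the
merged region is labelled by the sign of log2(me3 / me1) of the summed
per-million-normalized tag counts, with the tie (ratio exactly 0) going to
promoter.  Promoter regions intersecting an H3K27me3 island in the same
condition are flagged bivalent (poised).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, overlaps_any
from .synthetic import CONDITIONS

MARKS = ("H3K4me3", "H3K4me1", "H3K27me3")


def classify_regions(
    me3: pd.DataFrame,
    me1: pd.DataFrame,
    me3_total: int,
    me1_total: int,
    tie_label: str = "promoter",
) -> pd.DataFrame:
    """Merge H3K4me3/H3K4me1 islands into labelled regulatory regions.

    ``me3``/``me1`` have columns ``chrom, start, end, count``; totals are the
    mark library sizes used for per-million normalization.  Returns one row
    per maximal overlap group with columns ``chrom, start, end, label,
    me3_norm, me1_norm, log_ratio, bivalent`` (bivalent initialized False).
    """
    if me3_total <= 0 or me1_total <= 0:
        raise ValueError("mark library totals must be > 0")
    parts = []
    for mark, df, total in (("H3K4me3", me3, me3_total), ("H3K4me1", me1, me1_total)):
        d = df[["chrom", "start", "end", "count"]].copy()
        d["norm"] = d["count"] / total * 1e6
        d["mark"] = mark
        if len(d):
            parts.append(d)
    allisl = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=["chrom", "start", "end", "count", "norm", "mark"])
    )
    if len(allisl) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "label", "me3_norm", "me1_norm", "log_ratio", "bivalent"]
        )
    allisl = allisl.sort_values(["chrom", "start", "end"], kind="stable", ignore_index=True)
    # transitive >=1 bp overlap groups via running max end per chromosome
    group = np.zeros(len(allisl), dtype=np.int64)
    gid = -1
    rows = []
    for chrom, grp in allisl.groupby("chrom", sort=True, observed=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        new = np.empty(len(grp), dtype=bool)
        new[0] = True
        new[1:] = starts[1:] >= run_end[:-1]
        g = np.cumsum(new) - 1 + gid + 1
        gid = int(g[-1])
        group[grp.index.to_numpy()] = g
    allisl["_group"] = group
    agg = allisl.groupby("_group", sort=True).agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
    )
    norm = allisl.pivot_table(index="_group", columns="mark", values="norm", aggfunc="sum").reindex(agg.index)
    me3_norm = norm.get("H3K4me3", pd.Series(0.0, index=agg.index)).fillna(0.0).to_numpy()
    me1_norm = norm.get("H3K4me1", pd.Series(0.0, index=agg.index)).fillna(0.0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(me3_norm) - np.log2(me1_norm)
    label = np.where(
        me1_norm == 0,
        "promoter",
        np.where(
            me3_norm == 0,
            "enhancer",
            np.where(log_ratio > 0, "promoter", np.where(log_ratio < 0, "enhancer", tie_label)),
        ),
    )
    out = agg.reset_index(drop=True)
    out["label"] = label
    out["me3_norm"] = me3_norm
    out["me1_norm"] = me1_norm
    out["log_ratio"] = log_ratio
    out["bivalent"] = False
    return out


def call_bivalent(regions: pd.DataFrame, k27: pd.DataFrame) -> pd.DataFrame:
    """Flag promoter regions intersecting (>= 1 bp) any H3K27me3 island."""
    out = regions.copy()
    out["bivalent"] = False
    if len(out) == 0 or len(k27) == 0:
        return out
    for chrom, grp in out.groupby("chrom", observed=True):
        isl = k27[k27["chrom"] == chrom]
        if len(isl) == 0:
            continue
        ms, me = merge_intervals(isl["start"].to_numpy(), isl["end"].to_numpy())
        hit = overlaps_any(grp["start"].to_numpy(), grp["end"].to_numpy(), ms, me)
        out.loc[grp.index[hit & (grp["label"] == "promoter").to_numpy()], "bivalent"] = True
    return out


def match_promoter_state(
    promoters: pd.DataFrame,
    regions: pd.DataFrame,
    window: int = 2_000,
) -> np.ndarray:
    """Condition-1 epigenetic state of each CAGE promoter: ``active`` when a
    promoter-labelled region lies within +/- ``window`` bp, ``poised`` when
    that region is bivalent, ``no_island`` when none is in reach.  When both
    an active and a poised region are in reach the poised one wins (the
    bivalent signature is the informative one)."""
    state = np.full(len(promoters), "no_island", dtype=object)
    prom_regions = regions[regions["label"] == "promoter"]
    p_start = promoters["start"].to_numpy(dtype=np.int64)
    p_end = promoters["end"].to_numpy(dtype=np.int64)
    for chrom, grp in promoters.reset_index(drop=True).groupby("chrom", observed=True):
        reg = prom_regions[prom_regions["chrom"] == chrom]
        if len(reg) == 0:
            continue
        idx = grp.index.to_numpy()
        qs = p_start[idx] - window
        qe = p_end[idx] + window
        for bivalent, lab in ((False, "active"), (True, "poised")):
            sub = reg[reg["bivalent"] == bivalent]
            if len(sub) == 0:
                continue
            ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            hit = overlaps_any(qs, qe, ms, me)
            state[idx[hit]] = lab  # poised overwrites active by loop order
    return state


def classify_transitions(
    promoter_calls: pd.DataFrame,
    regions_cond1: pd.DataFrame,
    window: int = 2_000,
) -> tuple:
    """Cross the condition-1 epigenetic state with the CAGE regulation class.

    Returns ``(calls, table, poised_to_active)``: the input with an
    ``epi_state_cond1`` column; the 2x4 state x regulated-class count table
    (promoters without an island within the window are excluded); and the
    poised-to-active subset (poised in condition 1, CAGE class cond2_specific
    or up).
    """
    calls = promoter_calls.reset_index(drop=True).copy()
    calls["epi_state_cond1"] = match_promoter_state(calls, regions_cond1, window=window)
    classes = ["cond1_specific", "down", "up", "cond2_specific"]
    table = pd.DataFrame(0, index=["active", "poised"], columns=classes)
    sub = calls[calls["epi_state_cond1"].isin(["active", "poised"]) & calls["regulation"].isin(classes)]
    for (state, klass), n in sub.groupby(["epi_state_cond1", "regulation"], observed=True).size().items():
        table.loc[state, klass] = int(n)
    poised_to_active = calls[
        (calls["epi_state_cond1"] == "poised") & calls["regulation"].isin(["cond2_specific", "up"])
    ]
    return calls, table, poised_to_active


def region_signal(islands: pd.DataFrame, chrom: str, start: int, end: int, lib_total: int) -> float:
    """Interval-weighted island tag count inside ``[start, end)``, per million:
    each overlapping island contributes count x overlap/length."""
    if lib_total <= 0:
        raise ValueError("library total must be > 0")
    isl = islands[islands["chrom"] == chrom]
    if len(isl) == 0:
        return 0.0
    s = isl["start"].to_numpy(dtype=float)
    e = isl["end"].to_numpy(dtype=float)
    cnt = isl["count"].to_numpy(dtype=float)
    ov = np.clip(np.minimum(e, end) - np.maximum(s, start), 0, None)
    return float((cnt * ov / (e - s)).sum() / lib_total * 1e6)


def enhancer_specificity(regions_cond1: pd.DataFrame, regions_cond2: pd.DataFrame) -> pd.DataFrame:
    """Combined enhancer catalogue across the two conditions.

    Each enhancer-labelled region is ``common`` when it overlaps (>= 1 bp) an
    enhancer region of the other condition, else condition-specific.  Returns
    one row per input region with ``chrom, start, end, condition,
    specificity``.
    """
    rows = []
    enh = {
        "cond1": regions_cond1[regions_cond1["label"] == "enhancer"],
        "cond2": regions_cond2[regions_cond2["label"] == "enhancer"],
    }
    for cond, other in (("cond1", "cond2"), ("cond2", "cond1")):
        mine = enh[cond]
        if len(mine) == 0:
            continue
        common = np.zeros(len(mine), dtype=bool)
        for chrom, grp in mine.reset_index(drop=True).groupby("chrom", observed=True):
            oth = enh[other][enh[other]["chrom"] == chrom]
            if len(oth) == 0:
                continue
            ms, me = merge_intervals(oth["start"].to_numpy(), oth["end"].to_numpy())
            hit = overlaps_any(grp["start"].to_numpy(), grp["end"].to_numpy(), ms, me)
            common[grp.index.to_numpy()] = hit
        part = mine.reset_index(drop=True)[["chrom", "start", "end"]].copy()
        part["condition"] = cond
        part["specificity"] = np.where(common, "common", f"{cond}_specific")
        rows.append(part)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "condition", "specificity"])
    return pd.concat(rows, ignore_index=True)
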