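"""Recovery scoring of pipeline output against a planted truth set."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import PROMOTER_CLASSES, TruthSet


def match_promoters(truth: TruthSet, promoters: pd.DataFrame, slop: int = 20) -> pd.DataFrame:
    """For each planted promoter, the recovered promoter (same strand, planted
    TSS within the called interval +/- ``slop`` bp).  Returns one row per
    planted promoter with ``promoter_id`` (empty when missed) and the planted
    class; ties resolved to the closest dominant TSS."""
    rows = []
    for p in truth.promoters:
        sub = promoters[
            (promoters["chrom"] == p.chrom)
            & (promoters["strand"] == p.strand)
            & (promoters["start"] - slop <= p.tss)
            & (promoters["end"] + slop > p.tss)
        ]
        if len(sub) == 0:
            rows.append({"tss": p.tss, "chrom": p.chrom, "true_class": p.klass,
                         "bivalent": p.bivalent, "promoter_id": ""})
        else:
            best = sub.iloc[(sub["dominant_tss"] - p.tss).abs().argmin()]
            rows.append({"tss": p.tss, "chrom": p.chrom, "true_class": p.klass,
                         "bivalent": p.bivalent, "promoter_id": best["promoter_id"]})
    return pd.DataFrame(rows)


def promoter_recall(matches: pd.DataFrame) -> float:
    if len(matches) == 0:
        return float("nan")
    return float((matches["promoter_id"] != "").mean())


def regulation_macro_f1(matches: pd.DataFrame, calls: pd.DataFrame) -> float:
    """Macro-averaged F1 over the five regulation classes; an unrecovered
    planted promoter counts as a false negative of its class."""
    by_id = calls.set_index("promoter_id")["regulation"]
    pred = [
        by_id.get(pid, "missed") if pid else "missed"
        for pid in matches["promoter_id"]
    ]
    true = matches["true_class"].to_numpy()
    f1s = []
    for k in PROMOTER_CLASSES:
        tp = int(np.sum((true == k) & (np.array(pred) == k)))
        fp = int(np.sum((true != k) & (np.array(pred) == k)))
        fn = int(np.sum((true == k) & (np.array(pred) != k)))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 1.0)
    return float(np.mean(f1s))


def poised_to_active_recall(matches: pd.DataFrame, poised_to_active: pd.DataFrame) -> float:
    """Fraction of planted poised-to-active promoters (bivalent and planted
    up / cond2-specific) present in the called poised-to-active list."""
    target = matches[
        matches["bivalent"] & matches["true_class"].isin(["up", "cond2_specific"])
    ]
    if len(target) == 0:
        return float("nan")
    called = set(poised_to_active["promoter_id"])
    hit = [pid in called for pid in target["promoter_id"] if pid] + [False] * int(
        (target["promoter_id"] == "").sum()
    )
    return float(np.mean(hit))


def enhancer_recovery(truth: TruthSet, called: pd.DataFrame, slop: int = 100) -> dict:
    """Recall of planted transcribed enhancers and precision of the called
    bidirectional loci (a call is true when it overlaps a planted transcribed
    enhancer interval +/- ``slop``)."""
    planted = truth.transcribed_enhancers
    hits = np.zeros(len(planted), dtype=bool)
    call_true = np.zeros(len(called), dtype=bool)
    cs = called["start"].to_numpy() if len(called) else np.array([])
    ce = called["end"].to_numpy() if len(called) else np.array([])
    cc = called["chrom"].to_numpy() if len(called) else np.array([])
    for i, e in enumerate(planted):
        ov = (cc == e.chrom) & (cs < e.end + slop) & (ce > e.start - slop)
        if ov.any():
            hits[i] = True
            call_true |= ov
    recall = float(hits.mean()) if len(planted) else float("nan")
    precision = float(call_true.mean()) if len(called) else float("nan")
    return {"recall": recall, "precision": precision,
            "n_planted": len(planted), "n_called": len(called)}
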