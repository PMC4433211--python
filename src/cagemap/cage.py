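"""CAGE tag processing: multimap rescue weighting, Level-1 TSSs, Level-2 promoters.

Level-1 TSSs are single-base, strand-specific positions holding the weighted
number of CAGE tags mapping there.  Multi-mapping tags are rescued by
weighting each candidate location by the number of uniquely mapped tags in
the 200-bp window around it (same strand); when no candidate has unique
neighbours the weight falls back to 1/n.  Level-2 promoters chain Level-1
positions closer than 20 bp on the same strand and are kept when they reach
at least 10 tags per million in at least one condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import CONDITIONS

ALIGNMENT_COLUMNS = ("tag_id", "chrom", "pos", "strand")


def unique_position_counts(alignments: pd.DataFrame) -> pd.DataFrame:
    """Per-base counts of uniquely mapped tags (single-candidate tags only)."""
    uniq = alignments[alignments["n_candidates"] == 1]
    out = (
        uniq.groupby(["chrom", "strand", "pos"], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def assign_multimap_weights(
    alignments: pd.DataFrame,
    unique_counts: pd.DataFrame | None = None,
    window: int = 200,
) -> np.ndarray:
    """Per-candidate rescue weights, aligned with the rows of ``alignments``.

    For each tag, ``w_i = u_i / sum_j u_j`` where ``u_i`` is the number of
    uniquely mapped same-strand tags within the 200-bp window
    ``[pos - 100, pos + 100)`` around candidate ``i``; equal weights ``1/n``
    when every candidate's neighbourhood is empty of unique tags.  Weights of
    one tag always sum to 1.
    """
    if len(alignments) == 0:
        return np.zeros(0)
    for col in ALIGNMENT_COLUMNS:
        if col not in alignments.columns:
            raise ValueError(f"alignments missing column {col!r}")
    if unique_counts is None:
        unique_counts = unique_position_counts(alignments)
    half = window // 2

    # cumulative unique counts per (chrom, strand) for O(log n) window sums
    u = np.zeros(len(alignments))
    groups_idx = alignments.groupby(["chrom", "strand"], sort=False, observed=True).indices
    uc_idx = unique_counts.groupby(["chrom", "strand"], sort=False, observed=True).indices
    uc_pos = unique_counts["pos"].to_numpy()
    uc_cnt = unique_counts["count"].to_numpy()
    for key, rows in groups_idx.items():
        ui = uc_idx.get(key)
        if ui is None:
            continue
        pos_k = np.sort(uc_pos[ui])
        order = np.argsort(uc_pos[ui], kind="stable")
        cnt_k = uc_cnt[ui][order]
        cum = np.concatenate([[0], np.cumsum(cnt_k)])
        p = alignments["pos"].to_numpy()[rows]
        lo = np.searchsorted(pos_k, p - half, side="left")
        hi = np.searchsorted(pos_k, p + half, side="left")
        u[rows] = cum[hi] - cum[lo]

    tag = alignments["tag_id"].to_numpy()
    codes, _ = pd.factorize(tag)
    sums = np.bincount(codes, weights=u)
    n_cand = np.bincount(codes)
    s = sums[codes]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(s > 0, u / np.where(s > 0, s, 1.0), 1.0 / n_cand[codes])
    return w


def build_level1(alignments: pd.DataFrame, weights: np.ndarray) -> pd.DataFrame:
    """Sum candidate weights per (chrom, pos, strand).

    Positions whose weighted count is exactly zero (all-zero-weight decoys)
    are dropped; the total weighted count equals the number of tags.
    """
    df = alignments[["chrom", "pos", "strand"]].copy()
    df["count"] = np.asarray(weights, dtype=float)
    out = (
        df.groupby(["chrom", "strand", "pos"], sort=True, observed=True)["count"]
        .sum()
        .reset_index()
    )
    out = out[out["count"] > 0].reset_index(drop=True)
    return out[["chrom", "pos", "strand", "count"]]


def merge_level1_conditions(level1_by_cond: dict) -> pd.DataFrame:
    """Outer-join per-condition Level-1 tables on (chrom, pos, strand)."""
    merged = None
    for cond in CONDITIONS:
        df = level1_by_cond.get(cond)
        if df is None:
            continue
        df = df.rename(columns={"count": f"count_{cond}"})
        merged = df if merged is None else merged.merge(
            df, on=["chrom", "pos", "strand"], how="outer"
        )
    if merged is None:
        raise ValueError("no conditions supplied")
    for cond in CONDITIONS:
        col = f"count_{cond}"
        if col not in merged.columns:
            merged[col] = 0.0
        merged[col] = merged[col].fillna(0.0)
    merged = merged.sort_values(["chrom", "strand", "pos"], kind="stable", ignore_index=True)
    return merged


def normalize_tpm(level1: pd.DataFrame, library_totals: dict) -> pd.DataFrame:
    """Add ``tpm_<cond>`` columns: count / library total x 1e6.

    ``library_totals`` maps condition to the total number of weighted mapped
    tags in that condition's library.
    """
    out = level1.copy()
    for cond in CONDITIONS:
        total = library_totals.get(cond, 0)
        if f"count_{cond}" not in out.columns:
            continue
        if total <= 0:
            raise ValueError(f"library total for {cond} must be > 0")
        out[f"tpm_{cond}"] = out[f"count_{cond}"] / total * 1e6
    return out


def _check_sorted(level1: pd.DataFrame) -> None:
    key = level1[["chrom", "strand", "pos"]]
    if not key.equals(key.sort_values(["chrom", "strand", "pos"], kind="stable", ignore_index=False)):
        raise ValueError("level1 must be sorted by (chrom, strand, pos)")


def cluster_ids(level1: pd.DataFrame, max_gap: int = 20) -> np.ndarray:
    """Single-linkage cluster labels: same-strand positions < ``max_gap`` apart
    chain into one cluster.  Requires sorted input."""
    _check_sorted(level1)
    chrom = level1["chrom"].to_numpy()
    strand = level1["strand"].to_numpy()
    pos = level1["pos"].to_numpy()
    if len(level1) == 0:
        return np.zeros(0, dtype=np.int64)
    brk = np.empty(len(level1), dtype=bool)
    brk[0] = True
    brk[1:] = (chrom[1:] != chrom[:-1]) | (strand[1:] != strand[:-1]) | (np.diff(pos) >= max_gap)
    return np.cumsum(brk) - 1


def cluster_level2(
    level1: pd.DataFrame,
    max_gap: int = 20,
    min_tpm: float = 10.0,
) -> tuple:
    """Chain Level-1 TSSs into Level-2 CAGE promoters and apply the tpm filter.

    Returns ``(promoters, members)``:

    * ``promoters`` — one row per retained promoter with columns
      ``promoter_id, chrom, start, end, strand, dominant_tss, n_tss`` plus
      per-condition ``count_*`` and ``tpm_*`` sums;
    * ``members`` — ``level1`` with a ``promoter_id`` column (empty string for
      positions in discarded clusters).

    A promoter is retained iff its tpm reaches ``min_tpm`` in at least one
    condition.  The dominant TSS is the member with maximal pooled tpm, ties
    broken 5'-most on the promoter's strand.
    """
    members = level1.copy()
    cid = cluster_ids(members, max_gap=max_gap)
    members["_cluster"] = cid
    tpm_cols = [f"tpm_{c}" for c in CONDITIONS if f"tpm_{c}" in members.columns]
    count_cols = [f"count_{c}" for c in CONDITIONS if f"count_{c}" in members.columns]
    if not tpm_cols:
        raise ValueError("level1 has no tpm columns; call normalize_tpm first")
    agg = members.groupby("_cluster", sort=True).agg(
        chrom=("chrom", "first"),
        strand=("strand", "first"),
        start=("pos", "min"),
        end=("pos", "max"),
        n_tss=("pos", "size"),
        **{c: (c, "sum") for c in tpm_cols + count_cols},
    )
    agg["end"] = agg["end"] + 1  # half-open
    keep = agg[tpm_cols].max(axis=1) >= min_tpm
    agg = agg[keep]

    # dominant TSS on pooled tpm, tie -> 5'-most
    pooled = members[tpm_cols].sum(axis=1).to_numpy()
    dom = _dominant_per_cluster(members, pooled)
    agg["dominant_tss"] = agg.index.map(dom)

    id_by_cluster = {cl: f"P{i:06d}" for i, cl in enumerate(agg.index)}
    agg = agg.reset_index(drop=True)
    agg.insert(0, "promoter_id", [f"P{i:06d}" for i in range(len(agg))])
    members["promoter_id"] = members["_cluster"].map(id_by_cluster).fillna("")
    members = members.drop(columns="_cluster")
    cols = ["promoter_id", "chrom", "start", "end", "strand", "dominant_tss", "n_tss"] + tpm_cols + count_cols
    return agg[cols], members


def _dominant_per_cluster(members: pd.DataFrame, pooled: np.ndarray) -> dict:
    df = pd.DataFrame(
        {
            "_cluster": members["_cluster"].to_numpy(),
            "pos": members["pos"].to_numpy(),
            "strand": members["strand"].to_numpy(),
            "pooled": pooled,
        }
    )
    # 5'-most tie-break: sort by pooled desc then by 5'-ness, take first per cluster
    plus = df["strand"] == "+"
    df["tiebreak"] = np.where(plus, df["pos"], -df["pos"])
    df = df.sort_values(["_cluster", "pooled", "tiebreak"], ascending=[True, False, True], kind="stable")
    first = df.groupby("_cluster", sort=True).first()
    return first["pos"].to_dict()


def select_dominant_tss(member_positions, member_tpm, strand: str) -> int:
    """Dominant TSS of one promoter: maximal tpm, ties to the 5'-most position."""
    pos = np.asarray(member_positions)
    tpm = np.asarray(member_tpm, dtype=float)
    if pos.size == 0:
        raise ValueError("promoter has no members")
    best = tpm == tpm.max()
    cand = pos[best]
    return int(cand.min() if strand == "+" else cand.max())


# ---------------------------------------------------------------------------
# serialization


def write_ctss_bed(level1: pd.DataFrame, cond: str, path) -> None:
    """CTSS-style BED6; score = weighted count x 1000, rounded."""
    out = pd.DataFrame(
        {
            "chrom": level1["chrom"],
            "start": level1["pos"],
            "end": level1["pos"] + 1,
            "name": "ctss",
            "score": np.round(level1[f"count_{cond}"] * 1000).astype(np.int64),
            "strand": level1["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_level1_tsv(level1: pd.DataFrame, path) -> None:
    level1.to_csv(path, sep="\t", index=False)


def read_level1_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})


def write_promoters(promoters: pd.DataFrame, tsv_path, bed_path=None, thresholds: dict | None = None) -> None:
    with open(tsv_path, "w") as fh:
        for k, v in (thresholds or {}).items():
            fh.write(f"# {k}={v}\n")
        promoters.to_csv(fh, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": promoters["chrom"],
                "start": promoters["start"],
                "end": promoters["end"],
                "name": promoters["promoter_id"],
                "score": np.minimum(
                    np.round(promoters[[f"tpm_{c}" for c in CONDITIONS]].max(axis=1)), 1000
                ).astype(np.int64),
                "strand": promoters["strand"],
            }
        )
        bed.to_csv(bed_path, sep="\t", header=False, index=False)


def read_promoters(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", comment="#", dtype={"chrom": str, "strand": str})
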