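"""Synthetic CAGE libraries and histone-mark islands with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for a two-condition design (condition 1 = pluripotent-like state,
condition 2 = committed state):

* strand-specific 1-bp capped-tag positions clustered around planted TSSs,
  with overdispersed (negative-binomial) per-promoter counts,
* a configurable share of multi-mapping tags carrying 2-4 candidate
  locations of which exactly one is the true origin,
* low-level divergent (bidirectional) transcription at planted transcribed
  enhancers, with the minus-strand cluster 5' (left) of the plus-strand one,
* uniform background noise tags,
* H3K4me3 islands over planted promoter TSSs, H3K4me1 islands over planted
  enhancers, and H3K27me3 islands over planted bivalent promoters in
  condition 1 only.

Everything is driven by one seeded generator; the seed is recorded in the
truth file so any fixture can be regenerated bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, point_in_intervals
from .genome import GenomeModel

CONDITIONS = ("cond1", "cond2")

PROMOTER_CLASSES = ("common", "cond1_specific", "cond2_specific", "up", "down")


@dataclass(frozen=True)
class TruePromoter:
    chrom: str
    tss: int
    strand: str
    mean_tpm: tuple  # (condition-1 mean, condition-2 mean), tags per million
    klass: str  # one of PROMOTER_CLASSES
    gene_id: str = ""
    bivalent: bool = False  # poised (H3K4me3+/H3K27me3+) in condition 1


@dataclass(frozen=True)
class TrueEnhancer:
    chrom: str
    start: int
    end: int
    specificity: str  # "cond1" | "cond2" | "common"
    transcribed: bool
    center_minus: int = 0  # centre of the minus-strand eRNA cluster
    center_plus: int = 0


@dataclass
class TruthSet:
    promoters: list = field(default_factory=list)
    enhancers: list = field(default_factory=list)
    seed: int = 0

    @property
    def bivalent_promoters(self):
        return [p for p in self.promoters if p.bivalent]

    @property
    def transcribed_enhancers(self):
        return [e for e in self.enhancers if e.transcribed]

    def validate(self, model: GenomeModel) -> None:
        for p in self.promoters:
            if p.klass == "cond1_specific" and p.mean_tpm[1] != 0:
                raise ValueError("cond1-specific promoter with nonzero condition-2 mean")
            if p.klass == "cond2_specific" and p.mean_tpm[0] != 0:
                raise ValueError("cond2-specific promoter with nonzero condition-1 mean")
        # every transcribed enhancer must be clear of every gene TSS +/- 500 bp
        tss = np.array([g.tss for g in model.genes], dtype=np.int64)
        chroms = np.array([g.chrom for g in model.genes])
        for e in self.transcribed_enhancers:
            near = (chroms == e.chrom) & (tss >= e.start - 500) & (tss < e.end + 500)
            if near.any():
                raise ValueError("transcribed enhancer inside a TSS +/- 500 bp mask")


def plant_truth(
    model: GenomeModel,
    n_promoters: int,
    class_counts: dict | None = None,
    n_bivalent: int = 0,
    n_enhancers: int = 0,
    n_transcribed: int = 0,
    fold_change: float = 6.0,
    seed: int = 0,
) -> TruthSet:
    """Choose promoter/enhancer ground truth on top of a genome model.

    Promoters are planted at the TSSs of randomly chosen genes (so they are
    annotatable at distance 0); transcribed enhancers are placed in
    intergenic space >= 3 kb away from any gene span.  ``class_counts`` maps
    regulation classes to counts and must sum to ``n_promoters``; the default
    split is 10% specific per condition, 15% up, 15% down, rest common.
    Bivalent flags are planted on up / condition-2-specific promoters first
    (the poised-to-active population), then on common ones.
    """
    rng = np.random.default_rng(seed)
    if n_promoters > len(model.genes):
        raise ValueError("more planted promoters than genes")
    if class_counts is None:
        s = max(n_promoters // 10, 0)
        r = max(int(n_promoters * 0.15), 0)
        class_counts = {
            "cond1_specific": s, "cond2_specific": s, "up": r, "down": r,
            "common": n_promoters - 2 * s - 2 * r,
        }
    if sum(class_counts.values()) != n_promoters:
        raise ValueError("class_counts must sum to n_promoters")

    gene_idx = rng.choice(len(model.genes), size=n_promoters, replace=False)
    labels = np.concatenate([np.full(c, k) for k, c in class_counts.items()])
    rng.shuffle(labels)

    base = np.exp(rng.normal(np.log(200.0), 1.0, size=n_promoters))
    base = np.clip(base, 30.0, 5_000.0)
    m1 = base.copy()
    m2 = base.copy()
    m1[labels == "cond2_specific"] = 0.0
    m2[labels == "cond1_specific"] = 0.0
    m2[labels == "up"] *= fold_change
    m1[labels == "down"] *= fold_change
    # common rescale of both conditions so realized tpm sits near the planted
    # means (promoters carry ~95% of each library)
    scale = 2 * 950_000.0 / (m1.sum() + m2.sum())
    m1 *= scale
    m2 *= scale

    promoters = []
    for i, gi in enumerate(gene_idx):
        g = model.genes[gi]
        promoters.append(
            TruePromoter(
                chrom=g.chrom, tss=g.tss, strand=g.strand,
                mean_tpm=(float(m1[i]), float(m2[i])), klass=str(labels[i]),
                gene_id=g.gene_id,
            )
        )
    # bivalency: poised-to-active candidates first
    order = [i for i, p in enumerate(promoters) if p.klass in ("up", "cond2_specific")]
    order += [i for i, p in enumerate(promoters) if p.klass not in ("up", "cond2_specific")]
    if n_bivalent > len(promoters):
        raise ValueError("more bivalent flags than promoters")
    for i in order[:n_bivalent]:
        p = promoters[i]
        promoters[i] = TruePromoter(**{**asdict(p), "bivalent": True})

    enhancers = _plant_enhancers(model, n_enhancers, n_transcribed, rng)
    truth = TruthSet(promoters=promoters, enhancers=enhancers, seed=int(seed))
    truth.validate(model)
    return truth


def _plant_enhancers(model: GenomeModel, n_enhancers: int, n_transcribed: int, rng):
    if n_transcribed > n_enhancers:
        raise ValueError("n_transcribed exceeds n_enhancers")
    if n_enhancers == 0:
        return []
    margin = 3_000
    half = 300
    chrom_names = list(model.chrom_sizes)
    chrom_lens = np.array([model.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    forbidden = {}
    for c in chrom_names:
        spans = [(g.start - margin, g.end + margin) for g in model.genes if g.chrom == c]
        if spans:
            s, e = zip(*spans)
        else:
            s, e = [], []
        forbidden[c] = merge_intervals(np.array(s, dtype=np.int64), np.array(e, dtype=np.int64))
    placed = {c: [] for c in chrom_names}
    enhancers = []
    specs = np.concatenate([
        np.full(int(round(n_enhancers * 0.3)), "cond1"),
        np.full(int(round(n_enhancers * 0.3)), "cond2"),
    ])
    specs = np.concatenate([specs, np.full(n_enhancers - specs.size, "common")])
    rng.shuffle(specs)
    transcribed = np.zeros(n_enhancers, dtype=bool)
    transcribed[rng.choice(n_enhancers, size=n_transcribed, replace=False)] = True
    attempts = 0
    k = 0
    while k < n_enhancers:
        attempts += 1
        if attempts > 200 * n_enhancers:
            raise ValueError("could not place enhancers in intergenic space")
        ci = int(rng.integers(len(chrom_names)))
        chrom = chrom_names[ci]
        mid = int(rng.integers(margin + half, chrom_lens[ci] - margin - half))
        ms, me = forbidden[chrom]
        if point_in_intervals(np.array([mid - half, mid + half]), ms, me).any():
            continue
        if any(abs(mid - m) < 2_000 for m in placed[chrom]):
            continue
        placed[chrom].append(mid)
        enhancers.append(
            TrueEnhancer(
                chrom=chrom, start=mid - half, end=mid + half,
                specificity=str(specs[k]), transcribed=bool(transcribed[k]),
                center_minus=mid - 150, center_plus=mid + 150,
            )
        )
        k += 1
    enhancers.sort(key=lambda e: (e.chrom, e.start))
    return enhancers


# ---------------------------------------------------------------------------
# CAGE tag simulation


def _jitter(rng, n: int, sigma: float = 4.0, trunc: int = 20) -> np.ndarray:
    """Discretized Gaussian positional jitter truncated at +/- ``trunc`` bp."""
    return np.clip(np.round(rng.normal(0.0, sigma, size=n)), -trunc, trunc).astype(np.int64)


def _erna_strand_counts(rng, nb_size: float) -> tuple:
    """Per-strand tag counts for a transcribed enhancer: each >= 2 and with
    bounded imbalance so the locus is recoverable as balanced divergent
    transcription."""
    mean = 16.0
    total = int(rng.negative_binomial(nb_size, nb_size / (nb_size + mean)))
    total = max(total, 4)
    for _ in range(1000):
        plus = int(rng.binomial(total, 0.5))
        minus = total - plus
        if plus >= 2 and minus >= 2 and abs(plus - minus) / total <= 0.6:
            return plus, minus
    return total // 2, total - total // 2  # unreachable fallback


def simulate_cage_libraries(
    model: GenomeModel,
    truth: TruthSet,
    depth: int = 1_000_000,
    multimap_frac: float = 0.15,
    noise_rate: float = 1e-5,
    nb_size: float = 10.0,
    seed: int = 0,
):
    """Simulate two CAGE libraries of exactly ``depth`` tags each.

    Returns ``(alignments, truth)`` where ``alignments`` maps condition name
    to a DataFrame with one row per candidate location and columns
    ``tag_id`` (int), ``chrom``, ``pos``, ``strand``, ``n_candidates``.
    Tags are allocated: planted eRNA tags first, then ``round(noise_rate x
    genome length)`` uniform background tags, then the remainder across
    planted promoters multinomially with Gamma(``nb_size``) multipliers
    (i.e. negative-binomial promoter counts conditioned on the total).
    """
    if not (0 <= multimap_frac < 1):
        raise ValueError("multimap_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chrom_names = list(model.chrom_sizes)
    chrom_lens = np.array([model.chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    genome_len = int(chrom_lens.sum())
    chrom_offsets = np.concatenate([[0], np.cumsum(chrom_lens)])

    prom_tss = {c: np.sort([p.tss for p in truth.promoters if p.chrom == c]) for c in chrom_names}

    out = {}
    for cond_i, cond in enumerate(CONDITIONS):
        chroms_parts, pos_parts, strand_parts = [], [], []
        # --- planted eRNA tags
        for e in truth.transcribed_enhancers:
            if e.specificity in ("common", cond):
                plus, minus = _erna_strand_counts(rng, nb_size)
                pos_parts.append(e.center_plus + _jitter(rng, plus))
                strand_parts.append(np.full(plus, "+"))
                chroms_parts.append(np.full(plus, e.chrom))
                pos_parts.append(e.center_minus + _jitter(rng, minus))
                strand_parts.append(np.full(minus, "-"))
                chroms_parts.append(np.full(minus, e.chrom))
        n_erna = int(sum(p.size for p in pos_parts))
        # --- uniform background noise
        n_noise = int(round(noise_rate * genome_len))
        if n_noise:
            flat = rng.integers(0, genome_len, size=n_noise)
            ci = np.searchsorted(chrom_offsets, flat, side="right") - 1
            chroms_parts.append(np.array(chrom_names, dtype=object)[ci].astype(str))
            pos_parts.append(flat - chrom_offsets[ci])
            strand_parts.append(np.where(rng.random(n_noise) < 0.5, "+", "-"))
        # --- promoter tags fill the library to exactly `depth`
        remaining = depth - n_erna - n_noise
        if remaining < 0:
            raise ValueError("depth too small for planted eRNA + noise tags")
        means = np.array([p.mean_tpm[cond_i] for p in truth.promoters], dtype=float)
        active = means > 0
        if active.any() and remaining > 0:
            g = rng.gamma(nb_size, 1.0 / nb_size, size=int(active.sum()))
            w = means[active] * g
            counts = rng.multinomial(remaining, w / w.sum())
            for p, c in zip(np.array(truth.promoters, dtype=object)[active], counts):
                if c == 0:
                    continue
                pos_parts.append(p.tss + _jitter(rng, int(c)))
                strand_parts.append(np.full(int(c), p.strand))
                chroms_parts.append(np.full(int(c), p.chrom))
        elif remaining > 0:
            # nothing planted: emit the remainder as uniform background
            flat = rng.integers(0, genome_len, size=remaining)
            ci = np.searchsorted(chrom_offsets, flat, side="right") - 1
            chroms_parts.append(np.array(chrom_names, dtype=object)[ci].astype(str))
            pos_parts.append(flat - chrom_offsets[ci])
            strand_parts.append(np.where(rng.random(remaining) < 0.5, "+", "-"))

        if pos_parts:
            chrom = np.concatenate(chroms_parts)
            pos = np.concatenate(pos_parts)
            strand = np.concatenate(strand_parts)
        else:
            chrom = np.array([], dtype=str)
            pos = np.array([], dtype=np.int64)
            strand = np.array([], dtype=str)
        # clip jittered positions to chromosome bounds
        if pos.size:
            lens = pd.Series(chrom).map(model.chrom_sizes).to_numpy(dtype=np.int64)
            pos = np.clip(pos, 0, lens - 1)
        n_tags = pos.size

        # --- multi-mapping candidates
        is_multi = rng.random(n_tags) < multimap_frac
        n_cand = np.ones(n_tags, dtype=np.int64)
        n_cand[is_multi] = rng.integers(2, 5, size=int(is_multi.sum()))
        n_decoys = int((n_cand - 1).sum())
        decoy_chrom, decoy_pos = _draw_decoys(rng, n_decoys, chrom_names, chrom_lens, chrom_offsets, prom_tss)
        decoy_strand = np.where(rng.random(n_decoys) < 0.5, "+", "-")
        tag_id = np.arange(n_tags, dtype=np.int64)
        decoy_tag = np.repeat(tag_id, n_cand - 1)

        df = pd.DataFrame(
            {
                "tag_id": np.concatenate([tag_id, decoy_tag]),
                "chrom": np.concatenate([chrom, decoy_chrom]),
                "pos": np.concatenate([pos, decoy_pos]).astype(np.int64),
                "strand": np.concatenate([strand, decoy_strand]),
            }
        )
        df = df.sort_values(["tag_id", "chrom", "pos", "strand"], kind="stable", ignore_index=True)
        df["n_candidates"] = df["tag_id"].map(df["tag_id"].value_counts())
        out[cond] = df
    return out, truth


def _draw_decoys(rng, n: int, chrom_names, chrom_lens, chrom_offsets, prom_tss):
    """Uniform decoy locations >= 1 kb away from every planted promoter TSS."""
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    genome_len = int(chrom_lens.sum())
    filled = 0
    while filled < n:
        draw = rng.integers(0, genome_len, size=(n - filled) * 2 + 16)
        ci = np.searchsorted(chrom_offsets, draw, side="right") - 1
        p = draw - chrom_offsets[ci]
        ok = np.ones(draw.size, dtype=bool)
        for k, c in enumerate(chrom_names):
            tss = prom_tss[c]
            if tss.size == 0:
                continue
            sel = ci == k
            if not sel.any():
                continue
            idx = np.searchsorted(tss, p[sel])
            near = np.zeros(int(sel.sum()), dtype=bool)
            left = np.clip(idx - 1, 0, tss.size - 1)
            right = np.clip(idx, 0, tss.size - 1)
            near |= np.abs(p[sel] - tss[left]) < 1_000
            near |= np.abs(p[sel] - tss[right]) < 1_000
            ok[sel] &= ~near
        take = min(int(ok.sum()), n - filled)
        sel_idx = np.flatnonzero(ok)[:take]
        chroms[filled : filled + take] = np.array(chrom_names, dtype=object)[ci[sel_idx]]
        pos[filled : filled + take] = p[sel_idx]
        filled += take
    return chroms.astype(str), pos


# ---------------------------------------------------------------------------
# ChIP island simulation


def simulate_chip_islands(
    model: GenomeModel,
    truth: TruthSet,
    noise_islands: int = 0,
    seed: int = 0,
):
    """Emit SICER-style islands per mark per condition.

    Planted promoters get an H3K4me3 island spanning the TSS (both
    conditions); bivalent promoters additionally get an overlapping H3K27me3
    island in condition 1 only; enhancers get an H3K4me1 island in the
    condition(s) of their specificity; ``noise_islands`` random intervals with
    a random mark are added per condition.  Returns ``(islands, lib_totals)``
    where ``islands`` maps ``(mark, condition)`` to a DataFrame with columns
    ``chrom, start, end, count`` and ``lib_totals`` maps the same keys to the
    mark library size (sum of island tag counts).
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(model.chrom_sizes)
    rows = {(m, c): [] for m in ("H3K4me3", "H3K4me1", "H3K27me3") for c in CONDITIONS}

    def nb(mean, size=20.0):
        return max(1, int(rng.negative_binomial(size, size / (size + mean))))

    for p in truth.promoters:
        lo = max(0, p.tss - 1_000)
        hi = min(model.chrom_sizes[p.chrom], p.tss + 1_500)
        for cond in CONDITIONS:
            rows[("H3K4me3", cond)].append((p.chrom, lo, hi, nb(300)))
        if p.bivalent:
            k_lo = max(0, p.tss - 2_000)
            k_hi = min(model.chrom_sizes[p.chrom], p.tss + 2_000)
            rows[("H3K27me3", "cond1")].append((p.chrom, k_lo, k_hi, nb(200)))
    for e in truth.enhancers:
        lo = max(0, e.start - 500)
        hi = min(model.chrom_sizes[e.chrom], e.end + 500)
        conds = CONDITIONS if e.specificity == "common" else (e.specificity,)
        for cond in conds:
            rows[("H3K4me1", cond)].append((e.chrom, lo, hi, nb(100)))
    for cond in CONDITIONS:
        for _ in range(noise_islands):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            length = int(rng.integers(1_000, 3_000))
            start = int(rng.integers(0, model.chrom_sizes[chrom] - length))
            mark = ("H3K4me3", "H3K4me1", "H3K27me3")[int(rng.integers(3))]
            rows[(mark, cond)].append((chrom, start, start + length, nb(30)))

    islands, totals = {}, {}
    for key, rr in rows.items():
        df = pd.DataFrame(rr, columns=["chrom", "start", "end", "count"])
        df = df.sort_values(["chrom", "start", "end"], kind="stable", ignore_index=True)
        islands[key] = df
        totals[key] = max(int(df["count"].sum()), 1)
    return islands, totals


# ---------------------------------------------------------------------------
# serialization


def write_alignments_bed(df: pd.DataFrame, path) -> None:
    """BED6, one row per candidate location; name = tag id, score = number of
    candidate locations of that tag."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "name": "tag" + df["tag_id"].astype(str),
            "score": df["n_candidates"],
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_alignments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    tag_id, _ = pd.factorize(df["name"])
    out = pd.DataFrame(
        {"tag_id": tag_id, "chrom": df["chrom"], "pos": df["start"].astype(np.int64),
         "strand": df["strand"]}
    )
    out["n_candidates"] = out["tag_id"].map(out["tag_id"].value_counts())
    return out


def write_islands_bed(df: pd.DataFrame, mark: str, path) -> None:
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start"], "end": df["end"],
         "name": mark, "score": df["count"]}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_islands_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score"], dtype={"chrom": str},
    )
    return pd.DataFrame(
        {"chrom": df["chrom"], "start": df["start"].astype(np.int64),
         "end": df["end"].astype(np.int64), "count": df["score"].astype(np.int64)}
    )


def write_truth_json(truth: TruthSet, path) -> None:
    doc = {
        "seed": truth.seed,
        "promoters": [asdict(p) for p in truth.promoters],
        "enhancers": [asdict(e) for e in truth.enhancers],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth_json(path) -> TruthSet:
    doc = json.loads(Path(path).read_text())
    return TruthSet(
        promoters=[TruePromoter(**{**p, "mean_tpm": tuple(p["mean_tpm"])}) for p in doc["promoters"]],
        enhancers=[TrueEnhancer(**e) for e in doc["enhancers"]],
        seed=doc["seed"],
    )
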