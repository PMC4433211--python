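"""Shared helpers for the test suite: tiny frame builders and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def aln_frame(rows):
    """Alignment DataFrame from (tag_id, chrom, pos, strand) tuples."""
    df = pd.DataFrame(rows, columns=["tag_id", "chrom", "pos", "strand"])
    df["n_candidates"] = df["tag_id"].map(df["tag_id"].value_counts())
    return df


def level1_frame(rows, lib1=1_000_000, lib2=1_000_000):
    """Level-1 frame from (chrom, pos, strand, count1, count2) tuples, with tpm."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_cond1", "count_cond2"])
    df = df.sort_values(["chrom", "strand", "pos"], kind="stable", ignore_index=True)
    df["tpm_cond1"] = df["count_cond1"] / lib1 * 1e6
    df["tpm_cond2"] = df["count_cond2"] / lib2 * 1e6
    return df


def island_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# independent oracles


def cluster_oracle(positions, max_gap=20):
    """O(n^2) transitive closure of |p_i - p_j| < max_gap on one strand."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) < max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


def chi2_oracle(a, b, c, d):
    """Textbook sum((O-E)^2/E) over the 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
    return stat, float(stats.chi2.sf(stat, 1))


def nb_split_oracle(s1, s2, dispersion):
    """Brute-force conditional split test: null NB(mean n/2, given dispersion)
    per side (Poisson at dispersion 0); p sums splits at most as likely as the
    observed one, in plain probability space."""
    n = s1 + s2
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    if dispersion == 0:
        pmf = stats.poisson.pmf(k, n / 2.0)
    else:
        r = 1.0 / dispersion
        pmf = stats.nbinom.pmf(k, r, r / (r + n / 2.0))
    probs = [pmf[a] * pmf[n - a] for a in range(n + 1)]
    obs = probs[s1]
    total = sum(probs)
    return sum(p for p in probs if p <= obs * (1 + 1e-10)) / total


def binomial_split_oracle(s1, s2):
    """Exact binomial split test (equal libraries): splits of n with
    Binomial(n, 1/2) probability <= the observed split's."""
    n = s1 + s2
    if n == 0:
        return 1.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    obs = pmf[s1]
    return float(pmf[pmf <= obs * (1 + 1e-10)].sum())
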