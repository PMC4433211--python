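"""Two-condition statistics on tag counts.

* Pearson chi-square on the 2x2 table ``[[count, lib - count], ...]`` for
  differential promoter expression (no continuity correction by default).
* Regulation classing: condition-specific (zero tags in the other library),
  up / down (|log2 FC| above threshold), else common.
* A conditional negative-binomial exact test with fixed dispersion for
  lowly expressed bidirectional enhancer loci: under the null both
  library-scaled counts are NB with a common mean, and the p-value sums the
  probabilities of all splits of the observed total that are at most as
  likely as the observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CONDITIONS

REGULATION_CLASSES = ("cond1_specific", "cond2_specific", "up", "down", "common")


def chisq_test(count1, count2, lib1, lib2, correction: bool = False):
    """Pearson chi-square (1 df) on ``[[count1, lib1-count1], [count2, lib2-count2]]``.

    Vectorized over counts.  Degenerate tables (both counts zero, or a zero
    margin) return statistic 0 and p = 1 rather than raising.
    """
    a = np.asarray(count1, dtype=float)
    b = np.asarray(lib1, dtype=float) - a
    c = np.asarray(count2, dtype=float)
    d = np.asarray(lib2, dtype=float) - c
    if np.any(b < 0) or np.any(d < 0):
        raise ValueError("counts exceed library totals")
    n = a + b + c + d
    r1, r2 = a + c, b + d  # column margins (tag vs rest)
    c1, c2 = a + b, c + d  # row margins (libraries)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * (a * d - b * c) ** 2
        den = r1 * r2 * c1 * c2
        if correction:
            num = n * np.maximum(np.abs(a * d - b * c) - n / 2, 0.0) ** 2
        stat = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(stat == 0, 1.0, p)
    if np.ndim(count1) == 0:
        return float(stat), float(p)
    return stat, p


def classify_regulation(
    promoters: pd.DataFrame,
    library_totals: dict,
    fc_threshold_log2: float = np.log2(3.0),
    alpha: float = 0.01,
    min_tpm: float = 10.0,
    correction: bool = False,
) -> pd.DataFrame:
    """Differential calls for a Level-2 promoter table.

    Adds ``log2_fc`` (positive = higher in condition 2), ``chi2_stat``,
    ``p_value``, ``fdr`` (Benjamini-Hochberg, informational only) and
    ``regulation`` columns.  Condition-specific means zero weighted tags in
    the other library, at least ``min_tpm`` in its own, and p <= alpha;
    up/down means |log2 FC| >= threshold and p <= alpha; everything else is
    common.
    """
    out = promoters.copy()
    c1 = out[f"count_{CONDITIONS[0]}"].to_numpy(dtype=float)
    c2 = out[f"count_{CONDITIONS[1]}"].to_numpy(dtype=float)
    t1 = out[f"tpm_{CONDITIONS[0]}"].to_numpy(dtype=float)
    t2 = out[f"tpm_{CONDITIONS[1]}"].to_numpy(dtype=float)
    lib1 = library_totals[CONDITIONS[0]]
    lib2 = library_totals[CONDITIONS[1]]
    stat, p = chisq_test(c1, c2, lib1, lib2, correction=correction)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(t2) - np.log2(t1)
    sig = p <= alpha
    klass = np.full(len(out), "common", dtype=object)
    spec1 = (c2 == 0) & (t1 >= min_tpm) & sig
    spec2 = (c1 == 0) & (t2 >= min_tpm) & sig
    up = ~spec1 & ~spec2 & sig & (log2_fc >= fc_threshold_log2)
    down = ~spec1 & ~spec2 & sig & (log2_fc <= -fc_threshold_log2)
    klass[up] = "up"
    klass[down] = "down"
    klass[spec1] = "cond1_specific"
    klass[spec2] = "cond2_specific"
    out["log2_fc"] = log2_fc
    out["chi2_stat"] = stat
    out["p_value"] = p
    out["fdr"] = _bh_fdr(np.atleast_1d(p))
    out["regulation"] = klass
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# NB exact test


def _null_log_pmf(n: int, mean: float, dispersion: float) -> np.ndarray:
    """log pmf of one count under the null (NB with given mean/dispersion, or
    Poisson at dispersion 0) evaluated at 0..n."""
    k = np.arange(n + 1)
    if dispersion == 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    count1: float,
    count2: float,
    lib1: float,
    lib2: float,
    dispersion: float = 0.09,
) -> float:
    """Conditional exact test for two overdispersed counts with fixed dispersion.

    Counts are rescaled to the geometric mean of the two library sizes and
    rounded; conditioned on the scaled total ``n``, the p-value is the summed
    probability of every split ``(a, n - a)`` whose null probability does not
    exceed the observed split's, normalized by the total probability of the
    sum.  At ``dispersion == 0`` this reduces to the Poisson (binomial-split)
    conditional test.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if lib1 <= 0 or lib2 <= 0:
        raise ValueError("library sizes must be > 0")
    geo = float(np.sqrt(lib1 * lib2))
    s1 = int(round(count1 * geo / lib1))
    s2 = int(round(count2 * geo / lib2))
    n = s1 + s2
    if n == 0:
        return 1.0
    lp = _null_log_pmf(n, n / 2.0, dispersion)
    split = lp + lp[::-1]  # log P(a) + log P(n - a)
    obs = split[s1]
    # include ties up to a tiny relative tolerance in probability space
    keep = split <= obs + 1e-8
    m = split.max()
    total = np.exp(split - m)
    return float(total[keep].sum() / total.sum())


def nb_exact_test_many(count1, count2, lib1, lib2, dispersion: float = 0.09) -> np.ndarray:
    c1 = np.atleast_1d(np.asarray(count1, dtype=float))
    c2 = np.atleast_1d(np.asarray(count2, dtype=float))
    return np.array([nb_exact_test(a, b, lib1, lib2, dispersion) for a, b in zip(c1, c2)])


def call_differential_enhancers(
    enhancers: pd.DataFrame,
    library_totals: dict,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    dispersion: float = 0.09,
) -> pd.DataFrame:
    """Flag bidirectional CAGE-enhancer loci as up / down when the NB exact
    test gives p <= alpha and the library-scaled fold change is >= ``fc_min``."""
    out = enhancers.copy()
    if len(out) == 0:
        for col in ("nb_p", "scaled_fc", "call"):
            out[col] = []
        return out
    c1 = out[f"total_{CONDITIONS[0]}"].to_numpy(dtype=float)
    c2 = out[f"total_{CONDITIONS[1]}"].to_numpy(dtype=float)
    lib1 = library_totals[CONDITIONS[0]]
    lib2 = library_totals[CONDITIONS[1]]
    p = nb_exact_test_many(c1, c2, lib1, lib2, dispersion=dispersion)
    r1 = c1 / lib1
    r2 = c2 / lib2
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(r2 >= r1, r2 / np.where(r1 > 0, r1, np.nan), r1 / np.where(r2 > 0, r2, np.nan))
    fc = np.where((c1 == 0) & (c2 == 0), 1.0, np.where(np.isnan(fc), np.inf, fc))
    call = np.full(len(out), "ns", dtype=object)
    hit = (p <= alpha) & (fc >= fc_min)
    call[hit & (r2 > r1)] = "up"
    call[hit & (r1 > r2)] = "down"
    out["nb_p"] = p
    out["scaled_fc"] = fc
    out["call"] = call
    return out
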