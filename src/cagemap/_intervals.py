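"""Vectorized primitives for half-open genomic intervals on sorted numpy arrays."""

from __future__ import annotations

import numpy as np


def merge_intervals(starts, ends):
    """Union of half-open intervals ``[start, end)``.

    Returns merged ``(starts, ends)`` sorted by start. Touching intervals
    (end == next start) are kept separate, matching 1-bp-overlap semantics.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    running_end = np.maximum.accumulate(ends)
    # new block where start >= max end of everything before it
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] >= running_end[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = int(block_id[-1]) + 1
    out_starts = starts[new_block]
    out_ends = np.zeros(n_blocks, dtype=np.int64)
    np.maximum.at(out_ends, block_id, ends)
    return out_starts, out_ends


def overlaps_any(q_start, q_end, m_starts, m_ends):
    """For query intervals against MERGED sorted intervals: does each query
    overlap any interval by >= 1 bp?"""
    q_start = np.asarray(q_start, dtype=np.int64)
    q_end = np.asarray(q_end, dtype=np.int64)
    m_starts = np.asarray(m_starts, dtype=np.int64)
    m_ends = np.asarray(m_ends, dtype=np.int64)
    if m_starts.size == 0:
        return np.zeros(q_start.shape, dtype=bool)
    # candidate: last interval with start < q_end
    idx = np.searchsorted(m_starts, q_end, side="left") - 1
    idx_clip = np.clip(idx, 0, m_starts.size - 1)
    hit = (idx >= 0) & (m_ends[idx_clip] > q_start)
    return hit


def nearest_distance(q_start, q_end, m_starts, m_ends):
    """Distance (bp) from each query interval to the nearest merged interval;
    0 when overlapping or touching, +inf when the interval set is empty."""
    q_start = np.asarray(q_start, dtype=np.int64)
    q_end = np.asarray(q_end, dtype=np.int64)
    m_starts = np.asarray(m_starts, dtype=np.int64)
    m_ends = np.asarray(m_ends, dtype=np.int64)
    n = q_start.size
    if m_starts.size == 0:
        return np.full(n, np.inf)
    # gap to the nearest interval on the left (by start) and on the right
    right = np.searchsorted(m_starts, q_end, side="left")
    left = right - 1
    dist = np.full(n, np.inf)
    has_right = right < m_starts.size
    dist[has_right] = m_starts[right[has_right]] - q_end[has_right]
    has_left = left >= 0
    left_clip = np.clip(left, 0, m_starts.size - 1)
    left_gap = q_start - m_ends[left_clip]
    dist = np.where(has_left, np.minimum(dist, left_gap), dist)
    return np.maximum(dist, 0.0)


def point_in_intervals(pos, m_starts, m_ends):
    """Is each 1-bp position inside any merged sorted interval?"""
    return overlaps_any(pos, np.asarray(pos) + 1, m_starts, m_ends)
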