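"""Low-level interval arithmetic on sorted numpy arrays.

All coordinates are 0-based half-open.  Interval *unions* are represented as a
pair of equal-length arrays (starts, ends), sorted and pairwise disjoint.
Overlap joins between arbitrary (possibly overlapping) interval sets go
through NCLS, the nested-containment-list engine.
"""

from __future__ import annotations

import numpy as np
from ncls import NCLS


def merge_intervals(starts, ends):
    """Union of intervals -> sorted disjoint (starts, ends) arrays.

    Touching intervals ([0,10) and [10,20)) are merged; empty input yields
    empty arrays.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # running maximum of ends; a new block starts where start > max end so far
    cummax = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > cummax[:-1]
    block_id = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    del block_id
    return out_s, out_e


def subtract_interval(start, end, mask_starts, mask_ends):
    """Subtract a sorted disjoint union from one interval [start, end).

    Returns a list of (start, end) tuples, left to right.
    """
    if len(mask_starts) == 0:
        return [(start, end)]
    lo = int(np.searchsorted(mask_ends, start, side="right"))
    out = []
    cursor = start
    for i in range(lo, len(mask_starts)):
        ms, me = int(mask_starts[i]), int(mask_ends[i])
        if ms >= end:
            break
        if ms > cursor:
            out.append((cursor, ms))
        cursor = max(cursor, me)
        if cursor >= end:
            break
    if cursor < end:
        out.append((cursor, end))
    return out


def overlaps_union(q_starts, q_ends, u_starts, u_ends):
    """Boolean array: does each query interval share >=1 base with the union?

    The union must be sorted and disjoint.  Any-overlap rule.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if len(u_starts) == 0 or q_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    u_starts = np.asarray(u_starts, dtype=np.int64)
    u_ends = np.asarray(u_ends, dtype=np.int64)
    # first union interval ending after the query start
    idx = np.searchsorted(u_ends, q_starts, side="right")
    hit = idx < len(u_starts)
    hit[hit] = u_starts[idx[hit]] < q_ends[hit]
    return hit


def overlap_join(q_starts, q_ends, f_starts, f_ends):
    """All-pairs any-overlap join.

    Returns (query_idx, feature_idx) index arrays; features may overlap each
    other and a query can hit several features.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    f_starts = np.asarray(f_starts, dtype=np.int64)
    f_ends = np.asarray(f_ends, dtype=np.int64)
    if q_starts.size == 0 or f_starts.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    tree = NCLS(f_starts, f_ends, np.arange(f_starts.size, dtype=np.int64))
    q_idx, f_idx = tree.all_overlaps_both(
        q_starts, q_ends, np.arange(q_starts.size, dtype=np.int64)
    )
    return np.asarray(q_idx, dtype=np.int64), np.asarray(f_idx, dtype=np.int64)


def interval_set_by_chrom(df, chrom_col="chrom", start_col="start", end_col="end"):
    """Per-chromosome merged unions from a DataFrame of intervals."""
    out = {}
    for chrom, sub in df.groupby(chrom_col, observed=True, sort=False):
        out[str(chrom)] = merge_intervals(
            sub[start_col].to_numpy(), sub[end_col].to_numpy()
        )
    return out
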