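"""Exact integer interval arithmetic on 0-based half-open [start, end) spans.

Used for BED-style annotation tracks, merged-call accounting, and the
cross-scan union partition.  All functions accept iterables of (start, end)
pairs (optionally keyed by chromosome in dict form) and return sorted,
non-overlapping lists.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint half-open spans.

    Abutting intervals ([0, 5) and [5, 9)) are coalesced.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by the union of ``intervals``."""
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two interval sets (each unioned first)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    out = []
    i = j = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if s < e:
            out.append((s, e))
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference a \\ b on interval unions."""
    am, bm = merge_intervals(a), merge_intervals(b)
    out = []
    j = 0
    for s, e in am:
        cur = s
        while j < len(bm) and bm[j][1] <= cur:
            j += 1
        k = j
        while k < len(bm) and bm[k][0] < e:
            bs, be = bm[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def covers(intervals: Sequence[tuple[int, int]], position: int) -> bool:
    """True iff ``position`` falls inside any half-open interval.

    ``intervals`` must be sorted and disjoint (as produced by
    :func:`merge_intervals`); binary search.
    """
    lo, hi = 0, len(intervals)
    while lo < hi:
        mid = (lo + hi) // 2
        s, e = intervals[mid]
        if position < s:
            hi = mid
        elif position >= e:
            lo = mid + 1
        else:
            return True
    return False
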