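"""Closed-interval arithmetic shared by dereplication, host linkage, and
abundance masking.  Intervals are 1-based inclusive throughout."""

from __future__ import annotations


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals (adjacent intervals merge)."""
    if not intervals:
        return []
    ivs = sorted((min(a, b), max(a, b)) for a, b in intervals)
    merged = [ivs[0]]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def total_length(intervals: list[tuple[int, int]]) -> int:
    """Number of positions covered by the union of the intervals."""
    return sum(end - start + 1 for start, end in merge_intervals(intervals))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    lo = max(min(a), min(b))
    hi = min(max(a), max(b))
    return max(0, hi - lo + 1)
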