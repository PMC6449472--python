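"""Half-open interval arithmetic on (start, end) pairs.

All coordinates are 0-based half-open. Functions accept any iterable of
(start, end) pairs and return canonical (sorted, merged, non-overlapping)
lists of tuples. Kept deliberately small: every function here is checked
against a per-base set oracle in the test suite.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals: sorted, non-overlapping, non-adjacent-merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals)) if intervals else 0


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Set difference a \\ b; both are canonicalized first."""
    a = merge(a) if a else []
    b = merge(b) if b else []
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return total_length(a) - total_length(subtract(a, b))
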