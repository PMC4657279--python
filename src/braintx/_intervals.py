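"""Half-open interval arithmetic on a single linear sequence.

All intervals are 0-based half-open ``[start, end)`` pairs of ints.
Interval *sets* are represented as lists of disjoint, sorted, non-empty
pairs; :func:`merge` normalizes arbitrary input into this canonical form,
and the other operations require/preserve it.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Normalize into sorted, disjoint form, merging touching intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: List[Interval], b: List[Interval]) -> List[Interval]:
    """Set difference a \\ b; both must be canonical (see :func:`merge`)."""
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


def complement(a: List[Interval], length: int) -> List[Interval]:
    """Gaps of canonical ``a`` within ``[0, length)``."""
    return subtract([(0, int(length))], a)


def total_length(a: Iterable[Interval]) -> int:
    return sum(e - s for s, e in a)


def span(a: List[Interval]) -> Interval:
    if not a:
        raise ValueError("empty interval set has no span")
    return a[0][0], a[-1][1]
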