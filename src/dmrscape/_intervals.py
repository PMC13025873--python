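"""Half-open genomic interval arithmetic on numpy arrays.

All coordinates are 0-based, half-open ``[start, end)``. Interval sets are
represented as a pair of equal-length integer arrays ``(starts, ends)``,
assumed sorted by start after :func:`merge_intervals`.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts, ends):
    """Sort and merge overlapping or abutting intervals into a disjoint union."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlap_bp(q_start: int, q_end: int, starts, ends) -> int:
    """Total bases of ``[q_start, q_end)`` covered by a disjoint interval union."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0 or q_end <= q_start:
        return 0
    lo = np.maximum(starts, q_start)
    hi = np.minimum(ends, q_end)
    return int(np.maximum(hi - lo, 0).sum())


def subtract_intervals(starts_a, ends_a, starts_b, ends_b):
    """Set difference A \\ B for disjoint sorted interval unions A and B."""
    starts_a, ends_a = merge_intervals(starts_a, ends_a)
    starts_b, ends_b = merge_intervals(starts_b, ends_b)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(starts_a, ends_a):
        cur = s
        while j < len(starts_b) and ends_b[j] <= cur:
            j += 1
        k = j
        while k < len(starts_b) and starts_b[k] < e:
            if starts_b[k] > cur:
                out_s.append(cur)
                out_e.append(int(starts_b[k]))
            cur = max(cur, int(ends_b[k]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(int(e))
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def any_overlap(q_start: int, q_end: int, starts, ends) -> bool:
    """True iff ``[q_start, q_end)`` overlaps the interval set by >= 1 bp."""
    return overlap_bp(q_start, q_end, starts, ends) > 0
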