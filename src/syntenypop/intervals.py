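"""Half-open integer interval algebra.

Intervals are (N, 2) int64 arrays of [start, end) rows on a single
sequence. All operations return sorted, non-overlapping arrays unless
stated otherwise. This tiny kernel backs region merging, pan-genome
interval accounting and mask construction.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "total_length",
    "intersect",
    "intersect_many",
    "subtract",
    "complement",
    "clip",
    "filter_longer",
]


def as_intervals(iv) -> np.ndarray:
    """Coerce to an (N, 2) int64 array and validate start <= end."""
    arr = np.asarray(iv, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (N, 2) intervals, got shape {arr.shape}")
    if (arr[:, 1] < arr[:, 0]).any():
        raise ValueError("interval end < start")
    return arr


def merge(iv, merge_below: int = 1) -> np.ndarray:
    """Merge intervals whose gap (next.start - prev.end) is < merge_below.

    merge_below=1 gives plain set union on integer coordinates (touching
    intervals coalesce); larger values additionally bridge short gaps, as
    in hotspot-region merging.
    """
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s - out[-1][1] < merge_below:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.array(out, dtype=np.int64)


def total_length(iv) -> int:
    arr = merge(iv)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two interval sets."""
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def intersect_many(sets) -> np.ndarray:
    """Intersection of an iterable of interval sets (empty iterable invalid)."""
    sets = list(sets)
    if not sets:
        raise ValueError("intersect_many needs at least one interval set")
    acc = merge(sets[0])
    for s in sets[1:]:
        if len(acc) == 0:
            break
        acc = intersect(acc, s)
    return acc


def subtract(a, b) -> np.ndarray:
    """Portions of a not covered by b."""
    a = merge(a)
    b = merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def complement(iv, length: int) -> np.ndarray:
    """Gaps of iv within [0, length)."""
    return subtract(np.array([[0, int(length)]], dtype=np.int64), iv)


def clip(iv, start: int, end: int) -> np.ndarray:
    arr = merge(iv)
    if len(arr) == 0:
        return arr
    arr = arr.copy()
    arr[:, 0] = np.maximum(arr[:, 0], start)
    arr[:, 1] = np.minimum(arr[:, 1], end)
    return arr[arr[:, 0] < arr[:, 1]]


def filter_longer(iv, min_len: int) -> np.ndarray:
    """Keep intervals strictly longer than min_len bp."""
    arr = as_intervals(iv)
    if len(arr) == 0:
        return arr
    return arr[(arr[:, 1] - arr[:, 0]) > min_len]
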