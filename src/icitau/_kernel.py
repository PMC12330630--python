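"""Mergesort pair-census kernel.

The discordance count uses a bottom-up stable mergesort (Knight's algorithm):
after sorting jointly by (x, y), the number of strict inversions in y equals
the number of discordant pairs.  Tie runs are censused with numpy on the same
sorted views.  Everything here operates on dense float64 vectors with no NaN;
missing-value semantics live one layer up in :mod:`icitau.core`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, nogil=True)
def _merge_count(values: np.ndarray) -> int:
    """Count strict inversions in ``values`` via bottom-up mergesort."""
    n = values.size
    arr = values.copy()
    tmp = np.empty(n, dtype=arr.dtype)
    swaps = 0
    width = 1
    while width < n:
        start = 0
        while start < n:
            mid = min(start + width, n)
            end = min(start + 2 * width, n)
            i, j, k = start, mid, start
            while i < mid and j < end:
                if arr[j] < arr[i]:
                    tmp[k] = arr[j]
                    j += 1
                    swaps += mid - i
                else:
                    tmp[k] = arr[i]
                    i += 1
                k += 1
            while i < mid:
                tmp[k] = arr[i]
                i += 1
                k += 1
            while j < end:
                tmp[k] = arr[j]
                j += 1
                k += 1
            arr[start:end] = tmp[start:end]
            start += 2 * width
        width *= 2
    return swaps


def _tie_moments(sorted_equal_breaks: np.ndarray, n: int) -> tuple[int, float, float]:
    """Pair count and the two higher tie moments from a sorted-run break mask.

    Returns (sum t(t-1)/2, sum t(t-1)(t-2), sum t(t-1)(2t+5)) over run
    lengths t; the latter two feed the tie-corrected normal variance.
    """
    if n == 0:
        return 0, 0.0, 0.0
    idx = np.flatnonzero(sorted_equal_breaks)
    bounds = np.empty(idx.size + 2, dtype=np.int64)
    bounds[0] = 0
    bounds[1:-1] = idx + 1
    bounds[-1] = n
    t = np.diff(bounds).astype(np.float64)
    t = t[t > 1]
    if t.size == 0:
        return 0, 0.0, 0.0
    pairs = int((t * (t - 1) / 2).sum())
    m0 = float((t * (t - 1) * (t - 2)).sum())
    m1 = float((t * (t - 1) * (2 * t + 5)).sum())
    return pairs, m0, m1


def pair_census(x: np.ndarray, y: np.ndarray):
    """Full pair census of two equal-length, NaN-free float vectors.

    Returns a dict with n_tot, n_concordant, n_discordant, n_xtie, n_ytie,
    n_commontie and the tie moments (x0, x1, y0, y1) needed for the
    tie-corrected variance of tau-b.  O(n log n).
    """
    n = x.size
    n_tot = n * (n - 1) // 2
    perm = np.lexsort((y, x))
    xs = x[perm]
    ys = y[perm]
    xbreaks = xs[1:] != xs[:-1]
    jointbreaks = xbreaks | (ys[1:] != ys[:-1])
    n_xtie, x0, x1 = _tie_moments(xbreaks, n)
    n_commontie, _, _ = _tie_moments(jointbreaks, n)
    ysorted = np.sort(y)
    n_ytie, y0, y1 = _tie_moments(ysorted[1:] != ysorted[:-1], n)
    n_dis = int(_merge_count(ys))
    n_con = n_tot - n_xtie - n_ytie + n_commontie - n_dis
    return {
        "n_tot": n_tot,
        "n_concordant": n_con,
        "n_discordant": n_dis,
        "n_xtie": n_xtie,
        "n_ytie": n_ytie,
        "n_commontie": n_commontie,
        "x0": x0,
        "x1": x1,
        "y0": y0,
        "y1": y1,
    }
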