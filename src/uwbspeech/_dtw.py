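"""Dynamic-programming kernel for multi-dimensional DTW.

The pairwise cost is the L1 distance summed over feature columns; the DP
recursion uses the symmetric step set {(1,0), (0,1), (1,1)} anchored at
both ends, unnormalized.  A numba-compiled kernel is used when numba is
importable; a vectorized anti-diagonal numpy fallback gives identical
results otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _dtw_python(a: np.ndarray, b: np.ndarray) -> float:
    """Anti-diagonal vectorized DP; reference/fallback implementation."""
    i_n, j_n = a.shape[0], b.shape[0]
    cost = np.abs(a[:, None, :] - b[None, :, :]).sum(axis=2)
    acc = np.full((i_n + 1, j_n + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, i_n + 1):
        prev = acc[i - 1]
        row = acc[i]
        np.minimum(prev[1:], prev[:-1], out=row[1:])
        # row[j] also depends on row[j-1]; resolve left-to-right
        c = cost[i - 1]
        running = row[0]
        for j in range(1, j_n + 1):
            best = row[j]
            if running < best:
                best = running
            running = best + c[j - 1]
            row[j] = running
    return float(acc[i_n, j_n])


if _HAVE_NUMBA:

    @njit(cache=False)
    def _dtw_numba(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover
        i_n, j_n = a.shape[0], b.shape[0]
        k_n = a.shape[1]
        prev = np.empty(j_n + 1)
        cur = np.empty(j_n + 1)
        for j in range(j_n + 1):
            prev[j] = np.inf
        prev[0] = 0.0
        for i in range(1, i_n + 1):
            cur[0] = np.inf
            for j in range(1, j_n + 1):
                c = 0.0
                for k in range(k_n):
                    d = a[i - 1, k] - b[j - 1, k]
                    c += d if d >= 0 else -d
                best = prev[j]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                cur[j] = best + c
            prev, cur = cur, prev
        return prev[j_n]

    def dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
        return float(_dtw_numba(np.ascontiguousarray(a), np.ascontiguousarray(b)))

else:

    def dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
        return _dtw_python(a, b)
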