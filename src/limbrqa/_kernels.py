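"""Compiled streaming kernels for recurrence computations.

The recurrence plot of an N'-state embedding has N'^2 cells; sessions at
full scale reach tens of thousands of states, so the plot is never
materialized here. Both kernels walk the plot diagonal by diagonal in
O(N') memory, accumulating recurrent-cell counts and maximal diagonal-run
histograms directly from squared Euclidean distances.

Convention shared with the matrix-based reference path: cells with
|i - j| >= theiler are counted (theiler = 0 includes the main diagonal);
off-diagonal contributions are doubled for symmetry.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def diag_scan(X, eps2, theiler, lmin):
    """Recurrent-cell count, counted-cell count and diagonal-run histogram.

    Returns (recurrent, cells, hist) where hist[L] counts maximal diagonal
    runs of length L >= lmin (upper and lower triangles both counted).
    """
    n, d = X.shape
    hist = np.zeros(n + 1, dtype=np.int64)
    recurrent = 0
    cells = 0
    k0 = theiler if theiler > 0 else 0
    if theiler == 0:
        # main diagonal: zero distance everywhere, one run of length n
        recurrent += n
        cells += n
        if n >= lmin:
            hist[n] += 1
        k0 = 1
    for k in range(k0, n):
        length = n - k
        run = 0
        for i in range(length):
            d2 = 0.0
            for c in range(d):
                diff = X[i, c] - X[i + k, c]
                d2 += diff * diff
            if d2 <= eps2:
                recurrent += 2
                run += 1
            else:
                if run >= lmin:
                    hist[run] += 2
                run = 0
        if run >= lmin:
            hist[run] += 2
        cells += 2 * length
    return recurrent, cells, hist


@njit(cache=True)
def recurrence_count(X, eps2, theiler):
    """Recurrent / counted cell totals only (radius-calibration inner loop)."""
    n, d = X.shape
    recurrent = 0
    cells = 0
    k0 = theiler if theiler > 0 else 1
    if theiler == 0:
        recurrent += n
        cells += n
    for k in range(k0, n):
        length = n - k
        for i in range(length):
            d2 = 0.0
            for c in range(d):
                diff = X[i, c] - X[i + k, c]
                d2 += diff * diff
            if d2 <= eps2:
                recurrent += 2
        cells += 2 * length
    return recurrent, cells
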