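"""Low-level Gotoh dynamic-programming kernel for affine-cost global alignment.

The kernel minimises total penalty: a substitution column costs
``match`` (identical, non-N) or ``mismatch``; a gap run of length L costs
``gap_open + L * gap_extend``.  Terminal gaps are charged like any other
gap, so the alignment is truly global.

Compiled with numba when available; the pure-Python fallback is only
practical for short sequences.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


_BIG = 1e18
_EPS = 1e-9

# residue code for N (never counts as an identity)
N_CODE = 4

# traceback moves
DIAG = 0          # substitution column
GAP_IN_REF = 1    # query residue over a gap in the reference row
GAP_IN_QUERY = 2  # reference residue over a gap in the query row


@njit(cache=True)
def _fill(a, b, mismatch, gap_open, gap_extend, match):
    m = a.shape[0]
    n = b.shape[0]
    M = np.full((m + 1, n + 1), _BIG)
    X = np.full((m + 1, n + 1), _BIG)  # ends with gap in reference
    Y = np.full((m + 1, n + 1), _BIG)  # ends with gap in query
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = gap_open + i * gap_extend
    for j in range(1, n + 1):
        Y[0, j] = gap_open + j * gap_extend
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1] and ai != N_CODE:
                sub = match
            else:
                sub = mismatch
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] < prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] < prev:
                prev = Y[i - 1, j - 1]
            M[i, j] = sub + prev

            open_x = M[i - 1, j]
            if Y[i - 1, j] < open_x:
                open_x = Y[i - 1, j]
            open_x += gap_open + gap_extend
            ext_x = X[i - 1, j] + gap_extend
            X[i, j] = ext_x if ext_x < open_x else open_x

            open_y = M[i, j - 1]
            if X[i, j - 1] < open_y:
                open_y = X[i, j - 1]
            open_y += gap_open + gap_extend
            ext_y = Y[i, j - 1] + gap_extend
            Y[i, j] = ext_y if ext_y < open_y else open_y
    return M, X, Y


@njit(cache=True)
def _traceback(a, b, M, X, Y, mismatch, gap_open, gap_extend, match):
    """Recover one optimal path; ties prefer DIAG, then GAP_IN_REF, then
    GAP_IN_QUERY, and within gap runs the predecessor preference is M, X, Y."""
    m = a.shape[0]
    n = b.shape[0]
    cost = M[m, n]
    state = 0
    if X[m, n] < cost - _EPS:
        cost = X[m, n]
        state = 1
    if Y[m, n] < cost - _EPS:
        cost = Y[m, n]
        state = 2
    moves = np.empty(m + n, dtype=np.int8)
    k = 0
    i = m
    j = n
    n_identical = 0
    while i > 0 or j > 0:
        if state == 0:
            moves[k] = DIAG
            k += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != N_CODE:
                sub = match
                n_identical += 1
            else:
                sub = mismatch
            target = M[i, j] - sub
            i -= 1
            j -= 1
            if abs(M[i, j] - target) <= _EPS:
                state = 0
            elif abs(X[i, j] - target) <= _EPS:
                state = 1
            else:
                state = 2
        elif state == 1:
            moves[k] = GAP_IN_REF
            k += 1
            v = X[i, j]
            i -= 1
            if abs(M[i, j] + gap_open + gap_extend - v) <= _EPS:
                state = 0
            elif abs(X[i, j] + gap_extend - v) <= _EPS:
                state = 1
            else:
                state = 2
        else:
            moves[k] = GAP_IN_QUERY
            k += 1
            v = Y[i, j]
            j -= 1
            if abs(M[i, j] + gap_open + gap_extend - v) <= _EPS:
                state = 0
            elif abs(X[i, j] + gap_open + gap_extend - v) <= _EPS:
                state = 1
            else:
                state = 2
    return cost, n_identical, moves[:k][::-1].copy()


def align_encoded(a, b, mismatch, gap_open, gap_extend, match):
    """Align two uint8-encoded sequences; returns (cost, n_identical, moves)."""
    M, X, Y = _fill(a, b, mismatch, gap_open, gap_extend, match)
    return _traceback(a, b, M, X, Y, mismatch, gap_open, gap_extend, match)
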