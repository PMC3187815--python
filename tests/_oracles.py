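"""Independent oracles used by the tests.

These deliberately avoid the package's dynamic-programming kernel and
PCA path: alignment costs come from a top-down exhaustive search of the
alignment space (and, for tiny strings, literal enumeration of every
gapped alignment), PCA from a direct eigendecomposition of the
covariance matrix.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np


def score_columns(qa: str, ra: str, mismatch=1.0, gap_open=1.0, gap_extend=1.0,
                  match=0.0) -> float:
    """Cost of a given gapped alignment, scored column by column with
    affine gap runs (open charged at the first gap column of a run)."""
    cost = 0.0
    prev = None  # 'q' = gap in query row, 'r' = gap in ref row
    for qc, rc in zip(qa, ra):
        if qc == "-":
            cost += gap_extend + (gap_open if prev != "q" else 0.0)
            prev = "q"
        elif rc == "-":
            cost += gap_extend + (gap_open if prev != "r" else 0.0)
            prev = "r"
        else:
            cost += match if (qc == rc and qc != "N") else mismatch
            prev = None
    return cost


def enumerate_alignments(a: str, b: str):
    """Every global alignment of a and b as (gapped_a, gapped_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for qa, ra in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + qa, b[0] + ra
    if a:
        for qa, ra in enumerate_alignments(a[1:], b):
            yield a[0] + qa, "-" + ra
    if b:
        for qa, ra in enumerate_alignments(a, b[1:]):
            yield "-" + qa, b[0] + ra


def min_cost_enumerated(a: str, b: str, **params) -> float:
    """Minimum cost over literally every alignment (tiny strings only)."""
    return min(score_columns(qa, ra, **params) for qa, ra in enumerate_alignments(a, b))


def min_cost_search(a: str, b: str, mismatch=1.0, gap_open=1.0, gap_extend=1.0,
                    match=0.0) -> float:
    """Exhaustive top-down search of the alignment space with memoization
    on (position, open-gap state); equals min_cost_enumerated."""
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: int) -> float:
        # state: 0 = no open gap, 1 = gap open in ref row, 2 = in query row
        if i == len(a) and j == len(b):
            return 0.0
        best = float("inf")
        if i < len(a) and j < len(b):
            sub = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = min(best, sub + go(i + 1, j + 1, 0))
        if i < len(a):
            c = gap_extend + (gap_open if state != 1 else 0.0)
            best = min(best, c + go(i + 1, j, 1))
        if j < len(b):
            c = gap_extend + (gap_open if state != 2 else 0.0)
            best = min(best, c + go(i, j + 1, 2))
        return best

    return go(0, 0, 0)


def pca_by_eigendecomposition(X: np.ndarray):
    """Covariance PCA from scratch: eigendecomposition of the sample
    covariance of column-centered data.  Returns (scores, loadings,
    variance_fraction_percent) with the same sign convention as the
    package (largest-|loading| entry positive)."""
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order]
    for k in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[idx, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = centered @ loadings
    var_frac = 100.0 * eigvals / eigvals.sum()
    return scores, loadings, var_frac


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only mutation, uniform over the three alternatives."""
    bases = "ACGT"
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([x for x in bases if x != c]))
        else:
            out.append(c)
    return "".join(out)
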