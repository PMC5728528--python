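"""Independent oracles used by the test suite.

These deliberately avoid the package's implementation paths: a recursive
pure-Python aligner (memoized scorer + exhaustive path enumeration for
tiny inputs), connected-component clustering from an all-pairs identity
matrix, and a hand-written chi-square-of-proportions formula.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

MATCH, MISMATCH, GAP = 1, -1, -2

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def compatible(x: str, y: str) -> bool:
    return bool(_IUPAC[x] & _IUPAC[y])


def brute_force_best_score(a: str, b: str) -> int:
    """Optimal semi-global score by memoized recursion (free terminal gaps).

    Leading free gaps: start anywhere on one boundary; trailing free gaps:
    stop anywhere on the other.  Equivalent formulation: best over all
    (i, j) start/stop boundary pairs of the global score of the slices.
    """

    @lru_cache(maxsize=None)
    def inner(i: int, j: int) -> int:
        # best score of aligning a[i:] vs b[j:] where trailing overhang of
        # either sequence is free
        if i == len(a) or j == len(b):
            return 0
        sub = MATCH if compatible(a[i], b[j]) else MISMATCH
        return max(
            inner(i + 1, j + 1) + sub,
            inner(i + 1, j) + GAP,
            inner(i, j + 1) + GAP,
        )

    # leading overhang free: start at (i,0) or (0,j)
    best = 0  # empty alignment is admissible under free ends
    for i in range(len(a) + 1):
        best = max(best, inner(i, 0))
    for j in range(len(b) + 1):
        best = max(best, inner(0, j))
    return best


def enumerate_alignments(a: str, b: str):
    """All semi-global alignments of tiny sequences as (score, cols,
    matches) triples.  Exponential: keep len <= 8."""

    results = []

    def walk(i, j, score, cols, matches, started):
        if i == len(a) and j == len(b):
            results.append((score, cols, matches))
            return
        # trailing free gaps once the aligned block has ended: allowed by
        # consuming the remainder of either sequence for free
        if i < len(a) and j == len(b):
            results.append((score, cols, matches))
            return
        if j < len(b) and i == len(a):
            results.append((score, cols, matches))
            return
        m = compatible(a[i], b[j])
        walk(i + 1, j + 1, score + (MATCH if m else MISMATCH),
             cols + 1, matches + (1 if m else 0), True)
        walk(i + 1, j, score + GAP, cols + 1, matches, True)
        walk(i, j + 1, score + GAP, cols + 1, matches, True)

    # free leading gaps: every boundary start
    for i in range(len(a)):
        walk(i, 0, 0, 0, 0, False)
    for j in range(len(b)):
        walk(0, j, 0, 0, 0, False)
    results.append((0, 0, 0))  # fully-skipped (empty) alignment
    return results


def hamming_identity_pct(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def identity_with_coverage(align_fn, x: str, y: str, min_coverage: float = 0.9):
    """Identity of a pair, or 0.0 when the alignment spans less than
    `min_coverage` of the shorter sequence (mirrors the clustering rule
    that excludes high-identity micro-overlaps)."""
    res = align_fn(x, y)
    if res.aligned_cols < min_coverage * min(len(x), len(y)):
        return 0.0
    return res.identity_pct


def connected_component_count(sequences, identity_fn, threshold: float) -> int:
    """Number of connected components linking pairs at >= threshold."""
    n = len(sequences)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if identity_fn(sequences[i], sequences[j]) >= threshold:
            parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def chi2_proportions_oracle(successes, totals):
    """Textbook sum over the 2xk table of (O-E)^2/E, pooled expectation."""
    total_s = sum(successes)
    total_n = sum(totals)
    p = total_s / total_n
    if p in (0.0, 1.0):
        return 0.0
    chi2 = 0.0
    for s, n in zip(successes, totals):
        for obs, exp in ((s, n * p), (n - s, n * (1 - p))):
            chi2 += (obs - exp) ** 2 / exp
    return chi2


def equivalent_breakpoints(parent_a: str, parent_b: str, query: str) -> set[int]:
    """All breakpoints b where parent_a[:b] + parent_b[b:] == query
    (exhaustive scan oracle)."""
    return {
        b
        for b in range(len(query) + 1)
        if parent_a[:b] + parent_b[b: len(query)] == query
    }
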