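"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: alignment by exhaustive
enumeration, hypergeometric tails by direct summation with exact integer
binomials, sliding-window region detection by naive rescanning.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignments(a: str, b: str, gap_open=10.0, gap_extend=1.0):
    """All global alignments of two tiny sequences with affine-gap scores.

    Yields (score, matches) per alignment, counting matches as identical
    non-X aligned pairs. Exponential — only for sequences of length <= 8.
    """

    results: list[tuple[float, int]] = []

    def rec(i: int, j: int, score: float, matches: int, state: str) -> None:
        if i == len(a) and j == len(b):
            results.append((score, matches))
            return
        if i < len(a) and j < len(b):
            pair_score = _BLOSUM62[a[i], b[j]]
            rec(
                i + 1,
                j + 1,
                score + pair_score,
                matches + (1 if a[i] == b[j] and a[i] != "X" else 0),
                "M",
            )
        # affine convention: the opening cost covers the first gapped column,
        # extensions add gap_extend per further column
        if i < len(a):  # gap in b
            cost = gap_extend if state == "X" else gap_open
            rec(i + 1, j, score - cost, matches, "X")
        if j < len(b):  # gap in a
            cost = gap_extend if state == "Y" else gap_open
            rec(i, j + 1, score - cost, matches, "Y")

    rec(0, 0, 0.0, 0, "start")
    return results


def optimal_alignment_stats(a: str, b: str, gap_open=10.0, gap_extend=1.0):
    """(max score, set of match counts among score-optimal alignments)."""
    results = enumerate_alignments(a, b, gap_open, gap_extend)
    best = max(score for score, _ in results)
    matches = {m for score, m in results if score == best}
    return best, matches


def hypergeom_tail_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p for over-representation by direct summation.

    P(X >= a) where X ~ Hypergeom(N=a+b+c+d, K=a+b draws, k=a+c successes).
    Zero-margin tables return 1.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if min(row1, c + d, col1, b + d) == 0:
        return 1.0
    total = math.comb(n, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += math.comb(row1, k) * math.comb(n - row1, col1 - k) / total
    return min(p, 1.0)


def naive_kr_regions(sequence: str, window: int, min_fraction: float):
    """Reference K/R-rich region finder: rescan every window, merge by union."""
    n = len(sequence)
    covered = [False] * n
    for i in range(n - window + 1):
        chunk = sequence[i : i + window]
        if (chunk.count("K") + chunk.count("R")) / window >= min_fraction:
            for j in range(i, i + window):
                covered[j] = True
    regions = []
    start = None
    for i, flag in enumerate(covered + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((start + 1, i))
            start = None
    return regions


def hamming_identity(a: str, b: str) -> float:
    """Gapless identity over the shorter length (equal-length oracles only)."""
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "X")
    return matches / min(len(a), len(b))
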