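"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the alignment
oracle is a memoized recursion over all local alignments with affine gap
states; the hypergeometric oracle enumerates every draw.
"""

from functools import lru_cache
from itertools import combinations


def sw_oracle(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Optimal Smith-Waterman score by recursion over all alignment paths.

    ``score_fn(x, y)`` gives the substitution score; a gap of length k costs
    ``gap_open + k * gap_extend``.  A local alignment may start and end
    anywhere; the empty alignment scores 0.
    """

    @lru_cache(maxsize=None)
    def end_at(i: int, j: int, state: str) -> float:
        # best score of any alignment path ending at column (i, j) in `state`:
        # M = a[i-1] aligned to b[j-1]; I = gap in b (a consumed); D = gap in a
        if state == "M":
            if i == 0 or j == 0:
                return float("-inf")
            prev = max(0.0, end_at(i - 1, j - 1, "M"),
                       end_at(i - 1, j - 1, "I"), end_at(i - 1, j - 1, "D"))
            return prev + score_fn(a[i - 1], b[j - 1])
        if state == "I":
            if i == 0:
                return float("-inf")
            return max(
                max(end_at(i - 1, j, "M"), end_at(i - 1, j, "D"))
                - gap_open - gap_extend,
                end_at(i - 1, j, "I") - gap_extend,
            )
        if j == 0:
            return float("-inf")
        return max(
            max(end_at(i, j - 1, "M"), end_at(i, j - 1, "I"))
            - gap_open - gap_extend,
            end_at(i, j - 1, "D") - gap_extend,
        )

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            for state in "MID":
                best = max(best, end_at(i, j, state))
    return best


def hypergeom_oracle(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for d in draw if d in marked) >= x:
            hits += 1
    return hits / total
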