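"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive (exhaustive recursion / enumeration) and stay
independent of the library code paths they check.
"""

from functools import lru_cache


def levenshtein_recursive(a: str, b: str) -> int:
    """Exhaustive-recursion edit distance (memoized); only for short strings."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + cost)

    return rec(len(a), len(b))


def brute_force_medoid(group: list) -> str:
    """Member minimizing summed edit distance; ties by (length, lexicographic)."""
    best = None
    for cand in sorted(set(group), key=lambda s: (len(s), s)):
        total = sum(levenshtein_recursive(cand, other) for other in group)
        if best is None or total < best[0]:
            best = (total, cand)
    return best[1]


def brute_force_length_split(lengths: list) -> list:
    """Best 2-partition of sorted lengths minimizing within-group variance.

    Enumerates every 1-D split point; returns the two index groups (into the
    input list) of the minimizing split.
    """
    import numpy as np

    order = np.argsort(lengths, kind="stable")
    arr = np.asarray(lengths)[order]
    best = None
    for cut in range(1, len(arr)):
        lo, hi = arr[:cut], arr[cut:]
        score = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or score < best[0]:
            best = (score, cut)
    cut = best[1]
    return [sorted(order[:cut].tolist()), sorted(order[cut:].tolist())]


def naive_primer_positions(seq: str, primer: str, max_mm: int) -> list:
    """All start offsets where primer matches with <= max_mm mismatches (Hamming)."""
    hits = []
    for off in range(len(seq) - len(primer) + 1):
        mm = sum(1 for x, y in zip(seq[off : off + len(primer)], primer) if x != y)
        if mm <= max_mm:
            hits.append(off)
    return hits
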