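"""Independent oracles used by the tests.

These deliberately avoid the package's DP/bit-parallel implementations:
structures are enumerated exhaustively, the MFE is selected by a direct
recursive search applying the documented tie-break (prefer the pairing
branch, 5'-most partner), pair probabilities come from a brute-force
Boltzmann sum, and edit distances from the textbook Wagner-Fischer DP.
"""

import math
from collections import defaultdict
from functools import lru_cache

CANONICAL = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
}
MIN_LOOP = 3


def enumerate_structures(seq: str):
    """All non-crossing canonical structures (sets of 0-based pairs)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def structs(i, j):
        if j - i < MIN_LOOP + 1:
            return (frozenset(),)
        out = list(structs(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL:
                for a in structs(i + 1, k - 1):
                    for b in structs(k + 1, j):
                        out.append(a | b | {(i, k)})
        return tuple(out)

    return structs(0, n - 1) if n else (frozenset(),)


def mfe_structure(seq: str) -> frozenset:
    """Max-pairing structure with the documented deterministic tie-break,
    found by direct recursion (no DP matrix)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i < MIN_LOOP + 1:
            return (0, frozenset())
        # candidate: pair i with the 5'-most k achieving the maximum
        options = [best(i + 1, j)]
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL:
                ca, sa = best(i + 1, k - 1)
                cb, sb = best(k + 1, j)
                options.append((1 + ca + cb, sa | sb | {(i, k)}))
        target = max(c for c, _ in options)
        # prefer pairing; options after the first are in ascending k
        for c, s in options[1:]:
            if c == target:
                return (c, s)
        return options[0]

    return best(0, len(seq) - 1)[1]


def boltzmann(seq: str):
    """(partition function, pair-probability dict) by exhaustive summation
    at unit temperature with weight e per pair."""
    structures = enumerate_structures(seq)
    z = sum(math.e ** len(s) for s in structures)
    probs = defaultdict(float)
    for s in structures:
        w = math.e ** len(s) / z
        for p in s:
            probs[p] += w
    return z, dict(probs)


def levenshtein(a: str, b: str) -> int:
    """Wagner-Fischer unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
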