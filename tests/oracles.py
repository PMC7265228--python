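"""Independent reference implementations used to check the package.

These deliberately avoid the package's DP/scan code paths: alignment is a
memoized recursion over (position, position, previous-move) states; repeat
and RSS oracles are brute-force enumeration.
"""

from __future__ import annotations

import re
from functools import lru_cache

NEG = float("-inf")


def oracle_global_score(a: str, b: str, match=5, mismatch=-4, gap_open=-12, gap_extend=-2) -> int:
    """Best global affine-gap alignment score by exhaustive recursion."""
    la, lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == la and j == lb:
            return 0
        options = []
        if i < la and j < lb:
            s = match if a[i] == b[j] and a[i] != "N" else mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if i < la:
            g = gap_extend if prev == "X" else gap_open
            options.append(g + best(i + 1, j, "X"))
        if j < lb:
            g = gap_extend if prev == "Y" else gap_open
            options.append(g + best(i, j + 1, "Y"))
        return max(options)

    result = best(0, 0, "S")
    best.cache_clear()
    return int(result)


def oracle_local_score(a: str, b: str, **kw) -> int:
    """Best local score = max global score over all substring pairs (or 0)."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, oracle_global_score(a[i0:i1], b[j0:j1], **kw))
    return best


def oracle_semiglobal_score(a: str, b: str, **kw) -> int:
    """Overlap alignment: core must touch a sequence start and a sequence end."""
    la, lb = len(a), len(b)
    best = 0
    starts = [(i, 0) for i in range(la + 1)] + [(0, j) for j in range(lb + 1)]
    ends = [(i, lb) for i in range(la + 1)] + [(la, j) for j in range(lb + 1)]
    for i0, j0 in starts:
        for i1, j1 in ends:
            if i1 >= i0 and j1 >= j0:
                if i1 == i0 or j1 == j0:
                    best = max(best, 0)
                else:
                    best = max(best, oracle_global_score(a[i0:i1], b[j0:j1], **kw))
    return best


def oracle_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def oracle_canonical_rotation(u: str) -> str:
    return min(u[i:] + u[:i] for i in range(len(u)))


def oracle_exact_rss_positions(seq: str, heptamer: str, nonamer: str, spacer: int, side: str) -> list[int]:
    """Regex oracle for zero-mismatch RSS scanning on the top strand."""
    if side == "three_prime":
        pattern = f"(?=({re.escape(heptamer)}.{{{spacer}}}{re.escape(nonamer)}))"
    else:
        pattern = f"(?=({re.escape(nonamer)}.{{{spacer}}}{re.escape(heptamer)}))"
    return [m.start() for m in re.finditer(pattern, seq)]


def oracle_mismatch_rss_positions(
    seq: str, heptamer: str, nonamer: str, spacer: int, side: str, max_h: int, max_n: int
) -> list[int]:
    """Positional brute force for mismatch-tolerant RSS scanning."""
    hl, nl = len(heptamer), len(nonamer)
    footprint = hl + spacer + nl
    out = []
    for i in range(len(seq) - footprint + 1):
        if side == "three_prime":
            h = seq[i : i + hl]
            n = seq[i + hl + spacer : i + footprint]
        else:
            n = seq[i : i + nl]
            h = seq[i + nl + spacer : i + footprint]
        if oracle_hamming(h, heptamer) <= max_h and oracle_hamming(n, nonamer) <= max_n:
            out.append(i)
    return out


def is_primitive(u: str) -> bool:
    """True when the string is not a whole number of repeats of a shorter unit."""
    n = len(u)
    for d in range(1, n):
        if n % d == 0 and u[:d] * (n // d) == u:
            return False
    return True
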