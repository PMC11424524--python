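"""Independent reference implementations used only to check the package.

These deliberately share no code with the production paths: edit distance is
a full (unbanded) dynamic-programming matrix; the inverted-repeat scan is an
exhaustive search over all start pairs on the circle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@njit(cache=False)
def _dp_edit_distance(a: np.ndarray, b: np.ndarray) -> int:
    n, m = len(a), len(b)
    prev = np.arange(m + 1)
    cur = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev, cur = cur, prev
    return int(prev[m])


def edit_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance by the full DP matrix."""
    ea = np.array([_ENC[c] for c in a], dtype=np.int8)
    eb = np.array([_ENC[c] for c in b], dtype=np.int8)
    return _dp_edit_distance(ea, eb)


def brute_force_inverted_repeat(seq: str) -> tuple[int, int, int]:
    """Exhaustive scan for the longest inverted-repeat pair on a circle.

    Returns (i, j, length): seq[i+t mod n] == comp(seq[(j+L-1-t) mod n]) for
    all t, the two segments disjoint on the circle. Ties break on smaller
    (i, j). O(n^2 * L); use only on tiny instances.
    """
    n = len(seq)
    comp = [_COMP[c] for c in seq]
    best = (0, 0, 0)
    # parameterize by (i, e) = (first-copy start, second-copy END): growing L
    # keeps earlier pairings fixed (s[i+t] vs comp(s[e-t])), so matching and
    # disjointness are both monotone in L
    for i in range(n):
        for e in range(n):
            L = 0
            while (L < n
                   and seq[(i + L) % n] == comp[(e - L) % n]
                   and not _overlaps_circular(i, L + 1, (e - L) % n, L + 1, n)):
                L += 1
            j = (e - L + 1) % n
            if L > best[2] or (L == best[2] and (i, j) < (best[0], best[1])):
                best = (i, j, L)
    return best


def _overlaps_circular(i, li, j, lj, n) -> bool:
    occ = [False] * n
    for t in range(li):
        occ[(i + t) % n] = True
    return any(occ[(j + t) % n] for t in range(lj))
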