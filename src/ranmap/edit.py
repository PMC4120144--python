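"""Edit distance with threshold pruning.

Seed extension only ever asks "is the edit distance at most t?", so the
full quadratic DP is wasteful. ``bound_edit_distance`` evaluates the DP
restricted to the diagonal band |i - j| <= t and stops as soon as every
entry of the current row exceeds t, returning the sentinel t+1. Within the
budget it returns the exact distance, so

    d(x, y) <= t   iff   bound_edit_distance(x, y, t).value <= t,

which is all the aligner needs. ``full_edit_distance`` is the unpruned
reference. N is never equal to anything, itself included.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DistanceVerdict:
    """Outcome of a thresholded distance query.

    ``value`` is the exact distance when <= the queried t; otherwise the
    sentinel t+1 with ``exceeded`` set. ``cells`` counts DP cells evaluated
    (diagnostic for the pruning contract).
    """

    value: int
    exceeded: bool
    cells: int = 0


def _match(a: str, b: str) -> int:
    return 0 if (a == b and a != "N") else 1


def full_edit_distance(x: str, y: str) -> int:
    """Unit-cost Levenshtein distance (substitution/insertion/deletion)."""
    n, m = len(x), len(y)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        xc = x[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + _match(xc, y[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def bound_edit_distance(
    x: str, y: str, t: int, literal_init: bool = False
) -> DistanceVerdict:
    """Banded edit-distance DP that gives up once the distance must exceed t.

    Only cells with |i - j| <= t are evaluated; a row whose minimum exceeds
    t proves d(x, y) > t, and the sentinel t+1 is returned. With
    ``literal_init`` the first DP row and column are zero-initialized
    (free end gaps on both prefixes) instead of the standard 0..len ramp;
    this variant exists for studying the algorithm, not for alignment.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    n, m = len(x), len(y)
    inf = t + 1
    if not literal_init and abs(n - m) > t:
        # length difference alone forces more than t indels
        return DistanceVerdict(inf, True, 0)
    prev: dict[int, int] = {}
    for j in range(0, m + 1 if literal_init else min(m, t) + 1):
        prev[j] = 0 if literal_init else j
    cells = 0
    for i in range(1, n + 1):
        # the zero-initialized variant reproduces the printed DP exactly,
        # so it runs full-width rows; the standard form stays in the band
        lo, hi = (0, m) if literal_init else (max(0, i - t), min(m, i + t))
        if lo > hi:
            return DistanceVerdict(inf, True, cells)
        cur: dict[int, int] = {}
        row_min = inf
        if lo == 0:
            cur[0] = 0 if literal_init else i
            row_min = cur[0]
        xc = x[i - 1]
        for j in range(max(lo, 1), hi + 1):
            cells += 1
            v = min(
                prev.get(j - 1, inf) + _match(xc, y[j - 1]),
                prev.get(j, inf) + 1,
                cur.get(j - 1, inf) + 1,
            )
            cur[j] = v
            if v < row_min:
                row_min = v
        if row_min > t:
            return DistanceVerdict(inf, True, cells)
        prev = cur
    value = prev.get(m, inf)
    if value > t:
        return DistanceVerdict(inf, True, cells)
    return DistanceVerdict(value, False, cells)
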