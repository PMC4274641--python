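"""AWCII: exact enumeration of mutually-closed approximate weak common intervals.

For every left bound ``i`` of the index string and every right bound ``j``,
each position ``y`` of ``T_S`` carrying character ``j`` seeds at most
``(δ+1)²`` candidate intervals ``[k, l]``: for each left budget ``d_k`` the
leftmost position with at most ``d_k`` indels in ``[k, y]`` whose set meets
``[i, j]``, combined with the symmetric rightmost positions.  A candidate is
reported when the characters of ``[i, j]`` missing from ``C(T_S[k,l])`` plus
the indels already inside ``[k, l]`` stay within ``δ`` and ``[i, j]`` is
``C(T_S[k,l])``-closed.

Indels are counted on both sides: missing characters of ``[i, j]`` are
left-side indels, ``T_S`` positions in ``[k, l]`` whose set misses ``[i, j]``
are right-side indels.
"""

from __future__ import annotations

from typing import Sequence

from .core import (
    IndeterminateString,
    IndexMapping,
    Interval,
    IntervalPair,
    _occurs,
    classify_pair,
    index_mapping,
)
from .oracle import ResultSet

__all__ = [
    "candidate_bounds",
    "RangeContent",
    "ClosednessTable",
    "awcii_mapping",
    "awcii",
]


def _directional_bounds(
    tsi: Sequence[float], j: int, y: int, delta: int, step: int
) -> list[tuple[int, int]]:
    """Farthest positions reachable from ``y`` in one direction per indel budget.

    Returns unique ``(position, used_indels)`` pairs: for each budget
    ``d = 0..delta`` the outermost position ``p`` (leftmost for ``step=-1``,
    rightmost for ``step=+1``) such that ``tsi[p] ≤ j`` (the position's set
    meets ``[i, j]``) and the stretch between ``p`` and ``y`` contains at most
    ``d`` indels; ``used_indels`` is the exact count in that stretch.
    """
    m = len(tsi)
    best: dict[int, tuple[int, int]] = {}
    cnt = 0
    p = y
    while 1 <= p <= m:
        if tsi[p - 1] <= j:
            for d in range(cnt, delta + 1):
                best[d] = (p, cnt)
        else:
            cnt += 1
            if cnt > delta:
                break
        p += step
    return sorted(set(best.values()))


def candidate_bounds(
    ts: IndexMapping, i: int, j: int, y: int, delta: int, *, tsi: Sequence[float] | None = None
) -> list[tuple[int, int, int]]:
    """Candidate intervals ``(k, l, used_indels)`` around seed position ``y``.

    Precondition: ``j ∈ T_S[y]``.  At most ``(delta+1)²`` candidates are
    produced; each candidate's endpoints intersect ``[i, j]`` and
    ``used_indels`` is the exact number of positions in ``[k, l]`` whose set
    misses ``[i, j]``.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if j not in ts.at(y):
        raise ValueError(f"precondition violated: {j} not in T_S[{y}]")
    red = tsi if tsi is not None else ts.i_reduced(i)
    lefts = _directional_bounds(red, j, y, delta, -1)
    rights = _directional_bounds(red, j, y, delta, +1)
    seen: dict[tuple[int, int], int] = {}
    for k, uk in lefts:
        for l, ul in rights:
            if uk + ul <= delta:
                seen[(k, l)] = uk + ul
    return [(k, l, u) for (k, l), u in sorted(seen.items())]


class RangeContent:
    """Counts of characters of ``[i, j]`` present in ``C(T_S[k, l])``.

    Backed by per-character sorted position lists; each query is a pair of
    binary searches per character of ``[i, j]``.
    """

    def __init__(self, ts: IndexMapping, i: int, j: int, pos: dict[int, list[int]] | None = None):
        self.i, self.j = i, j
        self._pos = pos if pos is not None else ts.pos_table()

    def count(self, k: int, l: int) -> int:
        return sum(
            1 for c in range(self.i, self.j + 1) if _occurs(self._pos.get(c, ()), k, l)
        )

    def missing(self, k: int, l: int) -> int:
        return (self.j - self.i + 1) - self.count(k, l)


class ClosednessTable:
    """Whether character ``i - 1`` or ``j + 1`` occurs within a candidate interval."""

    def __init__(
        self, ts: IndexMapping, i: int, j: int, pos: dict[int, list[int]] | None = None
    ):
        self.i, self.j = i, j
        self.n = ts.source_len
        self._pos = pos if pos is not None else ts.pos_table()

    def blocked(self, k: int, l: int) -> bool:
        if self.i > 1 and _occurs(self._pos.get(self.i - 1, ()), k, l):
            return True
        if self.j < self.n and _occurs(self._pos.get(self.j + 1, ()), k, l):
            return True
        return False


def awcii_mapping(ts: IndexMapping, delta: int, min_size: int = 1) -> ResultSet:
    """All mutually-closed approximate weak common interval pairs of ``(I_S, T_S)``."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if min_size < 1:
        raise ValueError("min_size must be positive")
    n = ts.source_len
    pos = ts.pos_table()
    out = ResultSet()
    for i in range(1, n + 1):
        tsi = ts.i_reduced(i)
        absent = 0
        for j in range(i, n + 1):
            if j not in pos:
                absent += 1
                if absent > delta:
                    break  # every larger [i, j] misses > delta characters
                continue
            if absent > delta:
                break
            if j - i + 1 < min_size:
                continue
            content = RangeContent(ts, i, j, pos)
            closedness = ClosednessTable(ts, i, j, pos)
            candidates: dict[tuple[int, int], int] = {}
            for y in pos[j]:
                for k, l, used in candidate_bounds(ts, i, j, y, delta, tsi=tsi):
                    candidates[(k, l)] = used
            for (k, l), used in candidates.items():
                if l - k + 1 < min_size:
                    continue
                if not _occurs(pos.get(i, ()), k, l):
                    continue  # border i of [i,j] must intersect C(T_S[k,l])
                if closedness.blocked(k, l):
                    continue
                miss = content.missing(k, l)
                if miss + used > delta:
                    continue
                common = frozenset(
                    c for c in range(i, j + 1) if _occurs(pos.get(c, ()), k, l)
                )
                out.add(
                    IntervalPair(
                        left=Interval(i, j),
                        right=Interval(k, l),
                        common_set=common,
                        indels=miss + used,
                    )
                )
    return out


def awcii(
    s: IndeterminateString, t: IndeterminateString, delta: int, min_size: int = 1
) -> ResultSet:
    """All mutually-closed approximate weak common interval pairs of two strings."""
    ts = index_mapping(s, t)
    raw = awcii_mapping(ts, delta, min_size=min_size)
    out = ResultSet()
    for p in raw:
        cls = classify_pair(s, t, p.left, p.right)
        out.add(
            IntervalPair(
                left=p.left, right=p.right, common_set=cls.common_set, indels=cls.indels
            )
        )
    return out
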