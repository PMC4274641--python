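"""WCII: discovery of all mutually-closed weak common intervals (no indels).

The algorithm adapts Didier's common-interval search to indeterminate
strings.  It runs on the index string ``I_S`` and the index mapping ``T_S``:
for each left bound ``i`` it walks paths of *rank-nearest successors* through
``T_S`` (one level per right bound ``j``), keeps the outermost positions each
path has visited (*path bounds*), and reports the pair ``([i,j], [k,l])``
whenever the *min-rank interval* ``[k,l]`` of ``j`` around the current path
position encloses the path bounds and the borders ``i-1``/``j+1`` do not
occur in ``C(T_S[k,l])``.

Min-rank intervals of character ``j`` are maximal runs of positions whose
i-reduced entry is at most ``j``; they are maintained incrementally while
``j`` grows by merging adjacent runs (nested, as rank intervals are).

Paths that arrive at the same position are collapsed to the antichain of
bounds-minimal paths: a path whose bounds contain another path's bounds can
never report a pair the tighter one does not, since both share all future
positions.  This discontinuation rule keeps the traversal exact.
"""

from __future__ import annotations

from math import inf
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
    "rank_intervals",
    "MinRankTable",
    "update_min_rank",
    "nearest_successor",
    "rank_nearest_successors",
    "wcii_mapping",
    "wcii",
]


def rank_intervals(tsi: Sequence[float]) -> list[tuple[int, int] | None]:
    """Rank interval of character ``tsi[y]`` for every position ``y`` (1-based result list).

    The rank interval of ``c = tsi[y]`` at ``y`` is the largest interval
    around ``y`` whose entries are all ≤ ``c``.  Positions with an INF entry
    have no finite interval and map to ``None``.  Computed in O(m) with
    previous/next strictly-greater scans.
    """
    m = len(tsi)
    prev_greater = [0] * m  # 0-based index+1 of nearest left entry > tsi[y], else 0
    stack: list[int] = []
    for y in range(m):
        while stack and tsi[stack[-1]] <= tsi[y]:
            stack.pop()
        prev_greater[y] = stack[-1] + 1 if stack else 0
        stack.append(y)
    next_greater = [m + 1] * m
    stack.clear()
    for y in range(m - 1, -1, -1):
        while stack and tsi[stack[-1]] <= tsi[y]:
            stack.pop()
        next_greater[y] = stack[-1] + 1 if stack else m + 1
        stack.append(y)
    out: list[tuple[int, int] | None] = []
    for y in range(m):
        if tsi[y] == inf:
            out.append(None)
        else:
            out.append((prev_greater[y] + 1, next_greater[y] - 1))
    return out


class MinRankTable:
    """Min-rank intervals of the current character level, updated incrementally.

    At threshold ``t`` the table holds, for every position ``y`` with
    ``tsi[y] ≤ t``, the maximal run of consecutive positions with entries
    ≤ ``t`` that contains ``y`` — the min-rank interval of character ``t`` at
    ``y``.  Raising the threshold activates new positions and merges adjacent
    runs (union-find with path compression), mirroring the nestedness of rank
    intervals.
    """

    def __init__(self, tsi: Sequence[float], threshold: float | None = None):
        self.tsi = tuple(tsi)
        m = len(self.tsi)
        self._parent = list(range(m + 1))
        self._lo = list(range(m + 1))
        self._hi = list(range(m + 1))
        self._active = [False] * (m + 1)
        buckets: dict[float, list[int]] = {}
        for y, v in enumerate(self.tsi, start=1):
            if v != inf:
                buckets.setdefault(v, []).append(y)
        self._levels = sorted(buckets)
        self._buckets = buckets
        self._next_level = 0
        self.threshold: float = -inf
        if threshold is not None:
            self.advance_to(threshold)

    def _find(self, y: int) -> int:
        root = y
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[y] != root:
            self._parent[y], y = root, self._parent[y]
        return root

    def _union(self, a: int, b: int) -> None:
        ra, rb = self._find(a), self._find(b)
        if ra == rb:
            return
        self._parent[rb] = ra
        self._lo[ra] = min(self._lo[ra], self._lo[rb])
        self._hi[ra] = max(self._hi[ra], self._hi[rb])

    def _activate(self, y: int) -> None:
        self._active[y] = True
        if y > 1 and self._active[y - 1]:
            self._union(y, y - 1)
        if y < len(self.tsi) and self._active[y + 1]:
            self._union(y, y + 1)

    def advance_to(self, threshold: float) -> None:
        """Raise the character level; activates every position with entry ≤ threshold."""
        if threshold < self.threshold:
            raise ValueError("threshold may only increase")
        while self._next_level < len(self._levels) and self._levels[self._next_level] <= threshold:
            for y in self._buckets[self._levels[self._next_level]]:
                self._activate(y)
            self._next_level += 1
        self.threshold = threshold

    def interval(self, y: int) -> tuple[int, int] | None:
        """Min-rank interval of the current level character at ``y``, or None if inactive."""
        if not 1 <= y <= len(self.tsi):
            raise IndexError(f"position {y} out of range")
        if not self._active[y]:
            return None
        root = self._find(y)
        return (self._lo[root], self._hi[root])


def update_min_rank(table: MinRankTable, j: float) -> MinRankTable:
    """Advance ``table`` from character level ``j`` to ``j + 1`` (in place)."""
    table.advance_to(j + 1)
    return table


def nearest_successor(
    tsi: Sequence[float], candidates: Sequence[int], y: int
) -> int | None:
    """Rank-nearest successor of position ``y`` among ``candidates`` (sorted, 1-based).

    The successor is the candidate minimizing the min-rank distance
    ``max(tsi[p] for p between the two positions)``; ties go to the leftmost
    position.  Returns None when no candidate exists or the smallest distance
    is INF.
    """
    if not candidates:
        return None
    cand = set(candidates)
    best_d: float = inf
    best_y: int | None = None
    # right side: distance is non-decreasing while walking away
    run = tsi[y - 1]
    for p in range(y, len(tsi) + 1):
        run = max(run, tsi[p - 1])
        if run == inf:
            break
        if p in cand and run < best_d:
            best_d, best_y = run, p
    # left side: scan fully so the leftmost co-optimal candidate wins ties
    run = tsi[y - 1]
    for p in range(y, 0, -1):
        run = max(run, tsi[p - 1])
        if run == inf:
            break
        if p in cand and run <= best_d:
            best_d, best_y = run, p
    return best_y


def rank_nearest_successors(
    tsi: Sequence[float], pos: dict[int, list[int]]
) -> dict[tuple[int, int], int | None]:
    """Full SUCC table: rank-nearest successor for every (position, character) pair.

    Keys are ``(y, j)`` with ``j`` in ``T_S[y]``; the value is the position of
    the nearest ``j + 1``, or None.
    """
    succ: dict[tuple[int, int], int | None] = {}
    for j, ys in pos.items():
        nxt = pos.get(j + 1, [])
        for y in ys:
            succ[(y, j)] = nearest_successor(tsi, nxt, y)
    return succ


def _prune_antichain(bounds: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep only bounds not containing another bound (minimal antichain)."""
    uniq = sorted(set(bounds), key=lambda b: (-b[0], b[1]))
    kept: list[tuple[int, int]] = []
    best_hi = inf
    for lo, hi in uniq:  # lo descending: previous entries have lo >= current lo
        if hi < best_hi:
            kept.append((lo, hi))
            best_hi = hi
    return kept


def wcii_mapping(
    ts: IndexMapping, min_size: int = 1, stats: dict | None = None
) -> ResultSet:
    """All mutually-closed weak common interval pairs of ``(I_S, T_S)``.

    Returns interval pairs in index-mapping coordinates; the common character
    set of a reported pair ``([i,j], [k,l])`` is exactly ``[i, j]``.  When a
    ``stats`` dict is given, per-iteration processing counts are recorded
    under ``"processed"`` (each (position, character) of ``T_S`` at most once
    per left bound ``i``).
    """
    if min_size < 1:
        raise ValueError("min_size must be positive")
    n, m = ts.source_len, ts.m
    pos = ts.pos_table()
    out = ResultSet()
    if stats is not None:
        stats.setdefault("processed", {})
    for i in range(1, n + 1):
        leaves = pos.get(i)
        if not leaves:
            continue
        tsi = ts.i_reduced(i)
        table = MinRankTable(tsi, threshold=i)
        # LIST: current path position -> antichain of path bounds
        nodes: dict[int, list[tuple[int, int]]] = {y: [(y, y)] for y in leaves}
        j = i
        while nodes and j <= n:
            if stats is not None:
                for y in nodes:
                    key = (i, y, j)
                    stats["processed"][key] = stats["processed"].get(key, 0) + 1
            if j - i + 1 >= min_size:
                for y, blist in nodes.items():
                    iv = table.interval(y)
                    if iv is None:
                        continue
                    k, l = iv
                    if l - k + 1 < min_size:
                        continue
                    if not any(k <= lo and hi <= l for lo, hi in blist):
                        continue
                    if i > 1 and _occurs(pos.get(i - 1, ()), k, l):
                        continue
                    if j < n and _occurs(pos.get(j + 1, ()), k, l):
                        continue
                    out.add(
                        IntervalPair(
                            left=Interval(i, j),
                            right=Interval(k, l),
                            common_set=frozenset(range(i, j + 1)),
                            indels=0,
                        )
                    )
            if j == n:
                break
            nxt_pos = pos.get(j + 1, [])
            if not nxt_pos:
                break
            new_nodes: dict[int, list[tuple[int, int]]] = {}
            for y, blist in nodes.items():
                y2 = nearest_successor(tsi, nxt_pos, y)
                if y2 is None:
                    continue
                merged = new_nodes.setdefault(y2, [])
                for lo, hi in blist:
                    merged.append((min(lo, y2), max(hi, y2)))
            nodes = {y2: _prune_antichain(b) for y2, b in new_nodes.items()}
            j += 1
            update_min_rank(table, j - 1)
    return out


def wcii(
    s: IndeterminateString, t: IndeterminateString, min_size: int = 1
) -> ResultSet:
    """All mutually-closed weak common interval pairs of two indeterminate strings.

    Runs the index-mapping search and restates each reported pair in terms of
    the original alphabet (common character set over Σ).
    """
    ts = index_mapping(s, t)
    raw = wcii_mapping(ts, min_size=min_size)
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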