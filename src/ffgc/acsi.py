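"""ACSI: recursive-extension solver for approximate weak common intervals.

ACSI solves the same discovery problem as AWCII exactly, but organizes the
search around occurrences of the left bound character: for each ``i`` it
seeds a recursive EXTEND procedure at every position of ``T_S`` carrying
``i``.  EXTEND grows the current window ``[k, l]`` while its neighbours meet
``[i, j]``, aborts as soon as character ``i - 1`` or ``j + 1`` enters the
window's character set (no extension can then be closed), reports the window
when the characters of ``[i, j]`` missing from it fit the remaining indel
budget, and recurses across indel gaps on either side with budget
``d + k' + 1 - k`` (symmetrically on the right).

In practice this outperforms the level-wise searches because most seeds die
immediately; the output contract is nevertheless exactness, and a sound
candidate scan (:func:`candidate_j_scan`) only skips right bounds ``j`` that
provably cannot form a mutually-closed pair around the seed.
"""

from __future__ import annotations

from math import inf
from typing import Callable, Sequence

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

__all__ = ["extend", "candidate_j_scan", "acsi_mapping", "acsi"]


class _Ctx:
    __slots__ = ("tsi", "pos", "n", "m", "delta", "min_size", "sink")

    def __init__(self, tsi, pos, n, m, delta, min_size, sink):
        self.tsi = tsi
        self.pos = pos
        self.n = n
        self.m = m
        self.delta = delta
        self.min_size = min_size
        self.sink = sink


def _extend(ctx: _Ctx, i: int, j: int, k: int, l: int, d: int, depth: int) -> None:
    # each recursive call consumes at least one indel
    if depth > ctx.delta + 2:
        raise AssertionError("EXTEND recursion exceeded the indel budget bound")
    tsi, pos = ctx.tsi, ctx.pos
    # grow while the neighbours intersect [i, j]
    while k > 1 and tsi[k - 2] <= j:
        k -= 1
    while l < ctx.m and tsi[l] <= j:
        l += 1
    # abort: i-1 or j+1 inside the window can never be extended away
    if i > 1 and _occurs(pos.get(i - 1, ()), k, l):
        return
    if j < ctx.n and _occurs(pos.get(j + 1, ()), k, l):
        return
    missing = sum(1 for c in range(i, j + 1) if not _occurs(pos.get(c, ()), k, l))
    if (
        missing <= d
        and _occurs(pos.get(i, ()), k, l)
        and _occurs(pos.get(j, ()), k, l)
        and j - i + 1 >= ctx.min_size
        and l - k + 1 >= ctx.min_size
    ):
        ctx.sink(i, j, k, l, missing + (ctx.delta - d))
    # left jump across an indel gap
    p, gap = k - 1, 0
    while p >= 1 and tsi[p - 1] > j:
        p -= 1
        gap += 1
        if gap > d:
            break
    if p >= 1 and gap <= d and tsi[p - 1] <= j:
        _extend(ctx, i, j, p, l, d - gap, depth + 1)
    # right jump, symmetric
    q, gap = l + 1, 0
    while q <= ctx.m and tsi[q - 1] > j:
        q += 1
        gap += 1
        if gap > d:
            break
    if q <= ctx.m and gap <= d and tsi[q - 1] <= j:
        _extend(ctx, i, j, k, q, d - gap, depth + 1)


def extend(
    i: int,
    j: int,
    k: int,
    l: int,
    d: int,
    ts: IndexMapping,
    report_sink: Callable[[int, int, int, int, int], None],
    *,
    delta: int | None = None,
    min_size: int = 1,
) -> None:
    """Run the EXTEND recursion for fixed ``[i, j]`` from window ``[k, l]``.

    ``report_sink`` receives ``(i, j, k, l, indels)`` for every reported pair.
    ``delta`` defaults to ``d`` (a fresh budget).
    """
    if not (1 <= i <= j <= ts.source_len and 1 <= k <= l <= ts.m and d >= 0):
        raise ValueError("invalid EXTEND parameters")
    full = delta if delta is not None else d
    ctx = _Ctx(ts.i_reduced(i), ts.pos_table(), ts.source_len, ts.m, full, min_size, report_sink)
    _extend(ctx, i, j, k, l, d, 1)


def candidate_j_scan(
    y: int,
    i: int,
    ts: IndexMapping,
    delta: int,
    *,
    tsi: Sequence[float] | None = None,
    pos: dict[int, list[int]] | None = None,
) -> list[int]:
    """Sound over-approximation of right bounds ``j`` worth extending from seed ``y``.

    The maximal window ``W`` reachable from ``y`` — extending through
    positions that carry any character ≥ ``i`` and crossing at most ``delta``
    all-INF gaps per side — bounds every interval EXTEND can visit.  A right
    bound ``j`` is kept only if ``j`` occurs in ``C(T_S[W])`` and at most
    ``delta`` characters of ``[i, j]`` are absent from ``C(T_S[W])``; both
    conditions are necessary for any reported pair, so pruning never loses
    output.
    """
    red = tsi if tsi is not None else ts.i_reduced(i)
    table = pos if pos is not None else ts.pos_table()
    n, m = ts.source_len, ts.m
    wk = wl = y
    gaps = 0
    p = y - 1
    while p >= 1:
        if red[p - 1] == inf:
            gaps += 1
            if gaps > delta:
                break
        else:
            wk = p
        p -= 1
    gaps = 0
    p = y + 1
    while p <= m:
        if red[p - 1] == inf:
            gaps += 1
            if gaps > delta:
                break
        else:
            wl = p
        p += 1
    js: list[int] = []
    absent = 0
    for j in range(i, n + 1):
        if _occurs(table.get(j, ()), wk, wl):
            js.append(j)
        else:
            absent += 1
            if absent > delta:
                break
    return js


def acsi_mapping(
    ts: IndexMapping, delta: int, min_size: int = 1, *, prune: bool = True
) -> ResultSet:
    """All mutually-closed approximate weak common interval pairs of ``(I_S, T_S)``.

    Exactness is a hard contract despite the heuristic label; ``prune=False``
    disables the candidate-j scan and must yield identical results.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if min_size < 1:
        raise ValueError("min_size must be positive")
    n = ts.source_len
    pos = ts.pos_table()
    out = ResultSet()

    def sink(i: int, j: int, k: int, l: int, indels: int) -> None:
        out.add(
            IntervalPair(
                left=Interval(i, j),
                right=Interval(k, l),
                common_set=frozenset(
                    c for c in range(i, j + 1) if _occurs(pos.get(c, ()), k, l)
                ),
                indels=indels,
            )
        )

    for i in range(1, n + 1):
        seeds = pos.get(i)
        if not seeds:
            continue
        tsi = ts.i_reduced(i)
        for y in seeds:
            if prune:
                js = candidate_j_scan(y, i, ts, delta, tsi=tsi, pos=pos)
            else:
                js = range(i, n + 1)
            ctx = _Ctx(tsi, pos, n, ts.m, delta, min_size, sink)
            for j in js:
                _extend(ctx, i, j, y, y, delta, 1)
    return out


def acsi(
    s: IndeterminateString,
    t: IndeterminateString,
    delta: int,
    min_size: int = 1,
    *,
    prune: bool = True,
) -> ResultSet:
    """All mutually-closed approximate weak common interval pairs of two strings."""
    ts = index_mapping(s, t)
    raw = acsi_mapping(ts, delta, min_size=min_size, prune=prune)
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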