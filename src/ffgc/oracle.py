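"""Brute-force reference enumeration of mutually-closed (approximate) weak common intervals.

This module is the correctness reference for the WCII/AWCII/ACSI discovery
algorithms: it applies the definitions literally to *all* O(n²m²) interval
pairs.  The per-pair predicates are evaluated vectorized over numpy arrays so
the randomized equivalence batteries stay cheap; the arithmetic is a direct
transcription of the definitions, with no search strategy shared with the
algorithms it checks.

Performance is a non-goal here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .core import INF, IndeterminateString, Interval, IntervalPair

__all__ = ["ResultSet", "PairwiseClassification", "classify_all", "enumerate_bruteforce"]


class ResultSet:
    """A duplicate-free set of interval pairs in canonical order.

    Canonical order is ``(left.lo, left.hi, right.lo, right.hi)``; equality
    compares the coordinate sets (two runs that report the same interval pairs
    are equal even if scores or common sets were filled in differently).
    """

    def __init__(self, pairs: Iterable[IntervalPair] = ()):
        self._pairs: dict[tuple[int, int, int, int], IntervalPair] = {}
        for p in pairs:
            self.add(p)

    def add(self, pair: IntervalPair) -> None:
        self._pairs[pair.coords()] = pair

    def coords(self) -> frozenset[tuple[int, int, int, int]]:
        return frozenset(self._pairs)

    def __contains__(self, item) -> bool:
        if isinstance(item, IntervalPair):
            return item.coords() in self._pairs
        return tuple(item) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[IntervalPair]:
        return iter(sorted(self._pairs.values(), key=lambda p: p.coords()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResultSet):
            return NotImplemented
        return self.coords() == other.coords()

    def __hash__(self):
        return hash(self.coords())

    def get(self, coords: tuple[int, int, int, int]) -> IntervalPair | None:
        return self._pairs.get(coords)

    def __repr__(self) -> str:
        return f"ResultSet({len(self)} pairs)"


@dataclass
class PairwiseClassification:
    """Definitional statistics for every interval pair of two strings.

    ``s_intervals``/``t_intervals`` list the (lo, hi) coordinates, and the
    matrices are indexed ``[s_interval, t_interval]``.
    """

    s_intervals: np.ndarray  # (Na, 2) 1-based inclusive
    t_intervals: np.ndarray  # (Nb, 2)
    indels: np.ndarray  # (Na, Nb) int
    weak: np.ndarray  # (Na, Nb) bool
    mutually_closed: np.ndarray  # (Na, Nb) bool
    nonempty_common: np.ndarray  # (Na, Nb) bool
    _common: np.ndarray  # (Na, Nb, sigma) bool
    _alphabet: list

    def common_set(self, ai: int, bi: int) -> frozenset:
        cols = np.nonzero(self._common[ai, bi])[0]
        return frozenset(self._alphabet[c] for c in cols)


def _char_matrix(s: IndeterminateString, col: dict) -> np.ndarray:
    """Boolean position × character matrix; INF is excluded (matches nothing)."""
    a = np.zeros((len(s), len(col)), dtype=bool)
    for x, cs in enumerate(s):
        for c in cs:
            if c in col:
                a[x, col[c]] = True
    return a


def _interval_charsets(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All interval character sets of a position × character matrix.

    Returns the (N, 2) array of 1-based (lo, hi) coordinates and the
    (N, sigma) boolean matrix of their character sets.
    """
    n, sigma = a.shape
    coords = []
    rows = []
    for i in range(n):
        acc = np.logical_or.accumulate(a[i:], axis=0)
        for j in range(i, n):
            coords.append((i + 1, j + 1))
            rows.append(acc[j - i])
    if not coords:
        return np.zeros((0, 2), dtype=int), np.zeros((0, sigma), dtype=bool)
    return np.array(coords, dtype=int), np.array(rows, dtype=bool)


def classify_all(s: IndeterminateString, t: IndeterminateString) -> PairwiseClassification:
    """Evaluate the weak/approximate/mutually-closed predicates for all interval pairs."""
    col: dict = {}
    for st in (s, t):
        for cs in st:
            for c in cs:
                if c != INF and c not in col:
                    col[c] = len(col)
    alphabet = [None] * len(col)
    for c, idx in col.items():
        alphabet[idx] = c

    a_mat = _char_matrix(s, col)
    b_mat = _char_matrix(t, col)
    si, cs_rows = _interval_charsets(a_mat)
    ti, ct_rows = _interval_charsets(b_mat)
    na, nb = len(si), len(ti)
    sigma = len(col)
    if na == 0 or nb == 0:
        z = np.zeros((na, nb), dtype=bool)
        return PairwiseClassification(
            si, ti, z.astype(int), z, z, z, np.zeros((na, nb, sigma), dtype=bool), alphabet
        )

    # common character sets C = C(S[i,j]) ∩ C(T[k,l]) for every pair
    common = cs_rows[:, None, :] & ct_rows[None, :, :]  # (Na, Nb, sigma)
    nonempty = common.any(axis=2)

    # indels: positions of either interval whose set misses C entirely
    hit_s = np.tensordot(a_mat.astype(np.int16), common.astype(np.int16), axes=([1], [2])) > 0
    hit_t = np.tensordot(b_mat.astype(np.int16), common.astype(np.int16), axes=([1], [2])) > 0
    pref_s = np.zeros((len(s) + 1, na, nb), dtype=np.int16)
    np.cumsum(~hit_s, axis=0, out=pref_s[1:])
    pref_t = np.zeros((len(t) + 1, na, nb), dtype=np.int16)
    np.cumsum(~hit_t, axis=0, out=pref_t[1:])

    indels = np.zeros((na, nb), dtype=int)
    for ai in range(na):
        i, j = si[ai]
        indels[ai, :] += pref_s[j, ai, :] - pref_s[i - 1, ai, :]
    for bi in range(nb):
        k, l = ti[bi]
        indels[:, bi] += pref_t[l, :, bi] - pref_t[k - 1, :, bi]

    # mutual closedness: a is C(T[k,l])-closed on s, b is C(S[i,j])-closed on t.
    # Pad with all-False rows so border positions need no special-casing.
    mat_s_ct = np.zeros((len(s) + 2, nb), dtype=bool)
    mat_s_ct[1:-1] = a_mat @ ct_rows.T > 0  # position x of s intersects C(T[k,l])?
    mat_t_cs = np.zeros((len(t) + 2, na), dtype=bool)
    mat_t_cs[1:-1] = b_mat @ cs_rows.T > 0

    i_arr, j_arr = si[:, 0], si[:, 1]
    closed_s = (
        mat_s_ct[i_arr]
        & mat_s_ct[j_arr]
        & ~mat_s_ct[i_arr - 1]
        & ~mat_s_ct[j_arr + 1]
    )  # (Na, Nb)
    k_arr, l_arr = ti[:, 0], ti[:, 1]
    closed_t = (
        mat_t_cs[k_arr]
        & mat_t_cs[l_arr]
        & ~mat_t_cs[k_arr - 1]
        & ~mat_t_cs[l_arr + 1]
    ).T  # (Na, Nb)

    return PairwiseClassification(
        s_intervals=si,
        t_intervals=ti,
        indels=indels,
        weak=indels == 0,
        mutually_closed=closed_s & closed_t,
        nonempty_common=nonempty,
        _common=common,
        _alphabet=alphabet,
    )


def enumerate_bruteforce(
    s: IndeterminateString,
    t: IndeterminateString,
    delta: int = 0,
    min_size: int = 1,
    *,
    classification: PairwiseClassification | None = None,
) -> ResultSet:
    """All mutually-closed approximate weak common interval pairs with ≤ ``delta`` indels.

    Both intervals must span at least ``min_size`` positions; pairs with an
    empty common character set are never reported.  A precomputed
    ``classification`` (from :func:`classify_all` on the same strings) may be
    supplied to amortize repeated calls at different ``delta``.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if min_size < 1:
        raise ValueError("min_size must be positive")
    cls = classification if classification is not None else classify_all(s, t)
    if cls.indels.size == 0:
        return ResultSet()
    len_s = cls.s_intervals[:, 1] - cls.s_intervals[:, 0] + 1
    len_t = cls.t_intervals[:, 1] - cls.t_intervals[:, 0] + 1
    mask = (
        cls.mutually_closed
        & cls.nonempty_common
        & (cls.indels <= delta)
        & (len_s >= min_size)[:, None]
        & (len_t >= min_size)[None, :]
    )
    out = ResultSet()
    for ai, bi in np.argwhere(mask):
        i, j = cls.s_intervals[ai]
        k, l = cls.t_intervals[bi]
        out.add(
            IntervalPair(
                left=Interval(int(i), int(j)),
                right=Interval(int(k), int(l)),
                common_set=cls.common_set(ai, bi),
                indels=int(cls.indels[ai, bi]),
            )
        )
    return out
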