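"""Core domain types for (approximate) weak common intervals in indeterminate strings.

An *indeterminate string* (also called a degenerate string) is a sequence of
non-empty character sets over a finite alphabet.  Ordinary strings are the
special case where every position holds a singleton.  Two intervals, one in
each of two indeterminate strings, are *weak common intervals* if every
position of both intervals intersects the common character set
``C = C(S[i,j]) ∩ C(T[k,l])``; allowing up to ``delta`` positions with empty
intersection (*indels*) yields *approximate* weak common intervals.

All public coordinates are 1-based and inclusive.  The reserved sentinel
:data:`INF` marks positions of an index mapping that match nothing; it never
participates in any intersection and never occurs in a common character set.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, NamedTuple, Sequence

#: Reserved sentinel character, strictly greater than every alphabet character.
INF = math.inf

__all__ = [
    "INF",
    "IndeterminateString",
    "Interval",
    "IntervalPair",
    "IndexMapping",
    "PairClassification",
    "character_set",
    "cardinality",
    "is_closed",
    "classify_pair",
    "index_string",
    "index_mapping",
    "i_reduced",
    "min_rank_distance",
]


class IndeterminateString:
    """A sequence of non-empty character sets over a finite alphabet.

    Parameters
    ----------
    positions
        Iterable of iterables of characters.  Each position must be non-empty
        (Definition of an indeterminate string excludes the empty set).  The
        sentinel :data:`INF`, when present, must be the sole member of its
        position's set; such positions only arise in index mappings.
    """

    __slots__ = ("_sets",)

    def __init__(self, positions: Iterable[Iterable[Hashable]]):
        sets = []
        for idx, p in enumerate(positions, start=1):
            s = frozenset(p)
            if not s:
                raise ValueError(f"position {idx}: empty character set is not allowed")
            if INF in s and len(s) > 1:
                raise ValueError(
                    f"position {idx}: INF must be the sole member of its position"
                )
            sets.append(s)
        self._sets: tuple[frozenset, ...] = tuple(sets)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._sets)

    @property
    def n(self) -> int:
        """Number of positions ``|S|``."""
        return len(self._sets)

    def at(self, p: int) -> frozenset:
        """Character set at 1-based position ``p``."""
        if not 1 <= p <= len(self._sets):
            raise IndexError(f"position {p} out of range [1, {len(self._sets)}]")
        return self._sets[p - 1]

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self._sets)

    @property
    def positions(self) -> tuple[frozenset, ...]:
        return self._sets

    def cardinality(self) -> int:
        """Total number of elements ``‖S‖ = Σ |S[i]|``."""
        return sum(len(s) for s in self._sets)

    def character_set(self, lo: int = 1, hi: int | None = None) -> frozenset:
        """Union of position sets over ``[lo, hi]`` (defaults to the whole string)."""
        if hi is None:
            hi = len(self._sets)
        if len(self._sets) == 0 and lo == 1 and hi == 0:
            return frozenset()
        if not (1 <= lo <= hi <= len(self._sets)):
            raise IndexError(
                f"interval [{lo}, {hi}] out of range on string of length {len(self._sets)}"
            )
        return frozenset().union(*self._sets[lo - 1 : hi])

    def alphabet(self) -> frozenset:
        """All characters occurring in the string, including INF if present."""
        if not self._sets:
            return frozenset()
        return frozenset().union(*self._sets)

    def is_ordinary(self) -> bool:
        """True when every position is a singleton (an ordinary string)."""
        return all(len(s) == 1 for s in self._sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IndeterminateString):
            return NotImplemented
        return self._sets == other._sets

    def __hash__(self) -> int:
        return hash(self._sets)

    def __repr__(self) -> str:
        def fmt(s):
            return "{" + ",".join(sorted(map(str, s))) + "}"

        return "IndeterminateString(" + "".join(fmt(s) for s in self._sets) + ")"


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive index range ``[lo, hi]`` on one string."""

    lo: int
    hi: int
    string_id: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    def __len__(self) -> int:
        return self.hi - self.lo + 1

    def validate_on(self, s: "IndeterminateString | IndexMapping") -> "Interval":
        n = len(s)
        if self.hi > n:
            raise IndexError(
                f"interval [{self.lo}, {self.hi}] out of range on string of length {n}"
            )
        return self

    def positions(self) -> range:
        return range(self.lo, self.hi + 1)


@dataclass(frozen=True)
class IntervalPair:
    """A pair of intervals, one on each string, with its pair statistics.

    ``common_set`` is ``C = C(S[left]) ∩ C(T[right])`` with INF removed;
    ``indels`` counts the positions of both intervals whose set does not
    intersect ``C``.
    """

    left: Interval
    right: Interval
    common_set: frozenset = frozenset()
    indels: int = 0
    score: float | None = None

    def coords(self) -> tuple[int, int, int, int]:
        return (self.left.lo, self.left.hi, self.right.lo, self.right.hi)

    def __post_init__(self):
        if self.indels < 0:
            raise ValueError("indel count must be non-negative")
        if self.score is not None and self.score < 0:
            raise ValueError("score must be non-negative")


class PairClassification(NamedTuple):
    """Result of :func:`classify_pair`."""

    common_set: frozenset
    indels: int
    weak: bool
    mutually_closed: bool


def character_set(s: IndeterminateString, iv: Interval) -> frozenset:
    """Character set of the substring induced by ``iv`` (union of its position sets)."""
    iv.validate_on(s)
    return s.character_set(iv.lo, iv.hi)


def cardinality(s: IndeterminateString) -> int:
    """Number of all elements in ``s``: ``‖S‖ = Σ_i |S[i]|``."""
    return s.cardinality()


def is_closed(s: IndeterminateString, iv: Interval, c: Iterable[Hashable]) -> bool:
    """Whether ``iv`` is ``C``-closed on ``s``.

    ``[lo, hi]`` is C-closed iff both border positions intersect ``C`` and the
    interval cannot be extended: the left neighbour (if any) and the right
    neighbour (if any) have empty intersection with ``C``.  INF never belongs
    to ``C`` and is discarded if passed in.
    """
    iv.validate_on(s)
    cset = frozenset(c) - {INF}
    n = len(s)
    if not (s.at(iv.lo) & cset) or not (s.at(iv.hi) & cset):
        return False
    if iv.lo > 1 and (s.at(iv.lo - 1) & cset):
        return False
    if iv.hi < n and (s.at(iv.hi + 1) & cset):
        return False
    return True


def classify_pair(
    s: IndeterminateString,
    t: IndeterminateString,
    a: Interval,
    b: Interval,
) -> PairClassification:
    """Evaluate the defining predicates for the interval pair ``(a, b)``.

    Returns the common character set ``C``, the indel count, whether the pair
    is a weak common interval pair (no indels) and whether it is
    mutually-closed (``a`` is ``C(T[b])``-closed on ``s`` and ``b`` is
    ``C(S[a])``-closed on ``t``).  INF-only positions intersect nothing, hence
    always count as indels.
    """
    a.validate_on(s)
    b.validate_on(t)
    cs_a = s.character_set(a.lo, a.hi) - {INF}
    ct_b = t.character_set(b.lo, b.hi) - {INF}
    common = cs_a & ct_b
    indels = sum(1 for x in a.positions() if not (s.at(x) & common))
    indels += sum(1 for y in b.positions() if not (t.at(y) & common))
    weak = indels == 0
    mutually_closed = is_closed(s, a, ct_b) and is_closed(t, b, cs_a)
    return PairClassification(common, indels, weak, mutually_closed)


def index_string(n: int) -> IndeterminateString:
    """The index string ``I_S = {1}{2}…{n}``."""
    if n < 1:
        raise ValueError(f"index string length must be positive, got {n}")
    return IndeterminateString([{p} for p in range(1, n + 1)])


class IndexMapping:
    """An index mapping ``T_S`` of a string ``S`` (length ``n``) onto ``T``.

    Position ``y`` holds the sorted tuple of S-positions whose character set
    intersects ``T[y]``; an empty tuple encodes the ``{INF}`` position.
    Discovery algorithms run on ``(I_S, T_S)`` instead of ``(S, T)``:
    weak-common status, indel counts and mutual closedness carry over
    position-for-position.
    """

    __slots__ = ("_sets", "source_len", "provenance")

    def __init__(
        self,
        sets: Iterable[Iterable[int]],
        source_len: int,
        provenance: Sequence[Hashable] | None = None,
    ):
        norm = []
        for y, s in enumerate(sets, start=1):
            tup = tuple(sorted(set(s)))
            for x in tup:
                if not (isinstance(x, int) and 1 <= x <= source_len):
                    raise ValueError(
                        f"index mapping position {y}: character {x!r} outside [1, {source_len}]"
                    )
            norm.append(tup)
        self._sets: tuple[tuple[int, ...], ...] = tuple(norm)
        self.source_len = source_len
        self.provenance = tuple(provenance) if provenance is not None else None
        if self.provenance is not None and len(self.provenance) != len(self._sets):
            raise ValueError("provenance length must match mapping length")

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def m(self) -> int:
        return len(self._sets)

    def at(self, y: int) -> tuple[int, ...]:
        """Sorted characters at 1-based position ``y`` (empty tuple = {INF})."""
        if not 1 <= y <= len(self._sets):
            raise IndexError(f"position {y} out of range [1, {len(self._sets)}]")
        return self._sets[y - 1]

    @property
    def sets(self) -> tuple[tuple[int, ...], ...]:
        return self._sets

    def to_string(self) -> IndeterminateString:
        """The mapping as an indeterminate string over ``{1..n, INF}``."""
        return IndeterminateString([s if s else {INF} for s in self._sets])

    def pos_table(self) -> dict[int, list[int]]:
        """POS: for each character ``j``, the ascending positions containing it."""
        pos: dict[int, list[int]] = {}
        for y, s in enumerate(self._sets, start=1):
            for c in s:
                pos.setdefault(c, []).append(y)
        return pos

    def cardinality(self) -> int:
        """``‖T_S‖``: total element count (an INF position contributes one)."""
        return sum(len(s) if s else 1 for s in self._sets)

    def i_reduced(self, i: int) -> tuple[float, ...]:
        """The i-reduced string: per position the smallest character ≥ ``i``, else INF."""
        if not 1 <= i <= self.source_len:
            raise ValueError(f"i={i} out of range [1, {self.source_len}]")
        out = []
        for s in self._sets:
            k = bisect_left(s, i)
            out.append(s[k] if k < len(s) else INF)
        return tuple(out)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IndexMapping):
            return NotImplemented
        return self._sets == other._sets and self.source_len == other.source_len

    def __hash__(self) -> int:
        return hash((self._sets, self.source_len))

    def __repr__(self) -> str:
        body = "".join(
            "{" + (",".join(map(str, s)) if s else "INF") + "}" for s in self._sets
        )
        return f"IndexMapping({body}, n={self.source_len})"


def index_mapping(s: IndeterminateString, t: IndeterminateString) -> IndexMapping:
    """Index mapping of ``s`` onto ``t``: ``T_S[y] = {x : S[x] ∩ T[y] ≠ ∅}``.

    INF matches nothing, so INF-only positions of either string never
    contribute an intersection.
    """
    # invert s: character -> positions
    occ: dict[Hashable, list[int]] = {}
    for x, cs in enumerate(s, start=1):
        for c in cs:
            if c is not INF and c != INF:
                occ.setdefault(c, []).append(x)
    sets = []
    for ty in t:
        hit: set[int] = set()
        for c in ty:
            hit.update(occ.get(c, ()))
        sets.append(hit)
    return IndexMapping(sets, source_len=len(s))


def i_reduced(ts: IndexMapping, i: int) -> tuple[float, ...]:
    """Functional form of :meth:`IndexMapping.i_reduced`."""
    return ts.i_reduced(i)


def min_rank_distance(tsi: Sequence[float], k: int, l: int) -> float:
    """Min-rank distance ``d(k, l) = max(T_S^i[p] for k ≤ p ≤ l)``; INF-absorbing."""
    if not (1 <= k <= l <= len(tsi)):
        raise IndexError(f"range [{k}, {l}] out of bounds on length {len(tsi)}")
    return max(tsi[k - 1 : l])


def _occurs(pos_list: Sequence[int], k: int, l: int) -> bool:
    """Whether a sorted position list has an entry within ``[k, l]``."""
    idx = bisect_left(pos_list, k)
    return idx < len(pos_list) and pos_list[idx] <= l


def _count_in_range(pos_list: Sequence[int], k: int, l: int) -> int:
    return bisect_right(pos_list, l) - bisect_left(pos_list, k)
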