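"""Core types: strings, intervals, classification, index mappings."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffgc.core import (
    INF,
    IndeterminateString,
    IndexMapping,
    Interval,
    IntervalPair,
    cardinality,
    character_set,
    classify_pair,
    i_reduced,
    index_mapping,
    index_string,
    is_closed,
    min_rank_distance,
)
from ffgc.oracle import classify_all
from ffgc.synthetic import GenConfig, random_indeterminate_pair

from .conftest import EXAMPLE_TEXT, istr


# ---------------------------------------------------------------------------
# IndeterminateString fundamentals
# ---------------------------------------------------------------------------


class TestIndeterminateString:
    def test_worked_example_length_and_cardinality(self):
        s = istr(EXAMPLE_TEXT)
        assert len(s) == 6  # [TRIVIAL] count of printed positions
        assert s.cardinality() == 11  # [PAPER] stated cardinality of the example
        assert cardinality(s) == 11

    def test_worked_example_substring_character_set(self):
        s = istr(EXAMPLE_TEXT)
        # [PAPER] C(S[2,4]) is the union of {c}, {a,d}, {e,f}
        assert s.character_set(2, 4) == frozenset("acdef")
        assert character_set(s, Interval(2, 4)) == frozenset("acdef")
        assert s.character_set() == frozenset("abcdefg")
        assert s.alphabet() == frozenset("abcdefg")

    def test_position_access(self):
        s = istr(EXAMPLE_TEXT)
        assert s.at(1) == frozenset("adg")
        assert s.at(5) == frozenset("b")
        with pytest.raises(IndexError):
            s.at(0)
        with pytest.raises(IndexError):
            s.at(7)

    def test_empty_position_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            IndeterminateString([{"a"}, set(), {"b"}])

    def test_inf_must_be_sole_member(self):
        with pytest.raises(ValueError, match="INF"):
            IndeterminateString([{"a", INF}])
        s = IndeterminateString([{"a"}, {INF}])
        assert s.at(2) == frozenset({INF})

    def test_ordinary_detection(self):
        assert istr("a b c").is_ordinary()
        assert not istr("a,b c").is_ordinary()

    def test_equality_and_hash(self):
        assert istr("a,b c") == istr("b,a c")
        assert istr("a b") != istr("a c")
        assert hash(istr("a,b c")) == hash(istr("b,a c"))

    def test_interval_character_set_bounds_checked(self):
        s = istr("a b")
        with pytest.raises(IndexError):
            s.character_set(1, 3)
        with pytest.raises(IndexError):
            s.character_set(2, 1)


class TestInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            Interval(0, 2)
        with pytest.raises(ValueError):
            Interval(3, 2)
        iv = Interval(2, 4)
        assert len(iv) == 3
        assert list(iv.positions()) == [2, 3, 4]

    def test_validate_on(self):
        s = istr("a b c")
        Interval(1, 3).validate_on(s)
        with pytest.raises(IndexError):
            Interval(2, 4).validate_on(s)

    def test_pair_validation(self):
        with pytest.raises(ValueError):
            IntervalPair(Interval(1, 1), Interval(1, 1), indels=-1)
        with pytest.raises(ValueError):
            IntervalPair(Interval(1, 1), Interval(1, 1), score=-0.5)


# ---------------------------------------------------------------------------
# closedness and pair classification
# ---------------------------------------------------------------------------


class TestIsClosed:
    def test_worked_example_closed_interval(self):
        s = istr(EXAMPLE_TEXT)
        # [DERIVED] borders of [1,3] meet {a,c,d}; neighbour S[4]={e,f} does not
        assert is_closed(s, Interval(1, 3), {"a", "c", "d"})

    def test_extendable_interval_is_not_closed(self):
        s = istr(EXAMPLE_TEXT)
        # [DERIVED] left neighbour S[1]={a,d,g} intersects {a,c,d}
        assert not is_closed(s, Interval(2, 3), {"a", "c", "d"})

    def test_border_must_intersect(self):
        s = istr(EXAMPLE_TEXT)
        # [DERIVED] S[4]={e,f} has empty intersection with {a}
        assert not is_closed(s, Interval(4, 4), {"a"})
        assert not is_closed(s, Interval(3, 4), {"a"})

    def test_inf_is_discarded_from_c(self):
        s = IndeterminateString([{INF}, {"a"}, {INF}])
        assert is_closed(s, Interval(2, 2), {"a", INF})
        assert not is_closed(s, Interval(1, 1), {INF})

    def test_against_definition_bruteforce(self):
        rng = random.Random(7)
        for _ in range(30):
            cfg = GenConfig(seed=rng.randint(0, 10**6), n=8, m=8, alphabet_size=4)
            s, _ = random_indeterminate_pair(cfg)
            chars = sorted(s.alphabet())
            c = frozenset(rng.sample(chars, rng.randint(1, len(chars))))
            for lo in range(1, len(s) + 1):
                for hi in range(lo, len(s) + 1):
                    expected = (
                        bool(s.at(lo) & c)
                        and bool(s.at(hi) & c)
                        and (lo == 1 or not (s.at(lo - 1) & c))
                        and (hi == len(s) or not (s.at(hi + 1) & c))
                    )
                    assert is_closed(s, Interval(lo, hi), c) == expected


class TestClassifyPair:
    def test_full_match(self):
        s, t = istr("a b"), istr("a b")
        cls = classify_pair(s, t, Interval(1, 2), Interval(1, 2))
        assert cls.common_set == frozenset("ab")
        assert cls.indels == 0
        assert cls.weak
        assert cls.mutually_closed

    def test_singleton_pair(self):
        s, t = istr("a b"), istr("a b")
        cls = classify_pair(s, t, Interval(1, 1), Interval(1, 1))
        assert cls.common_set == frozenset("a")
        assert cls.weak and cls.mutually_closed

    def test_one_indel_breaks_weakness(self):
        s, t = istr("a b"), istr("a b")
        cls = classify_pair(s, t, Interval(1, 1), Interval(1, 2))
        # [DERIVED] C = {a}; T[2]={b} misses it (1 indel); T side extendable on S
        assert cls.common_set == frozenset("a")
        assert cls.indels == 1
        assert not cls.weak
        assert not cls.mutually_closed

    def test_indel_in_the_middle(self):
        s, t = istr("a x b"), istr("a b")
        cls = classify_pair(s, t, Interval(1, 3), Interval(1, 2))
        assert cls.common_set == frozenset("ab")
        assert cls.indels == 1
        assert cls.mutually_closed

    def test_symmetry(self):
        rng = random.Random(11)
        for _ in range(25):
            cfg = GenConfig(seed=rng.randint(0, 10**6), n=7, m=6, alphabet_size=4)
            s, t = random_indeterminate_pair(cfg)
            a = Interval(*sorted(rng.sample(range(1, len(s) + 1), 2)))
            b = Interval(*sorted(rng.sample(range(1, len(t) + 1), 2)))
            fwd = classify_pair(s, t, a, b)
            rev = classify_pair(t, s, b, a)
            assert fwd.common_set == rev.common_set
            assert fwd.indels == rev.indels
            assert fwd.mutually_closed == rev.mutually_closed


# ---------------------------------------------------------------------------
# index strings and index mappings
# ---------------------------------------------------------------------------


class TestIndexStructures:
    def test_index_string(self):
        i4 = index_string(4)
        assert len(i4) == 4
        assert i4.is_ordinary()
        assert [s for s in i4] == [frozenset({p}) for p in range(1, 5)]
        with pytest.raises(ValueError):
            index_string(0)

    def test_index_mapping_example(self):
        # [DERIVED] S = {a,b}{c}, T = {c}{a}{d}: c hits S[2], a hits S[1], d nothing
        s, t = istr("a,b c"), istr("c a d")
        ts = index_mapping(s, t)
        assert ts.sets == ((2,), (1,), ())
        assert ts.at(3) == ()
        assert ts.to_string().at(3) == frozenset({INF})
        assert ts.cardinality() == 3  # the INF position contributes one element
        assert len(ts) == 3 and ts.source_len == 2

    def test_index_mapping_ignores_inf_positions(self):
        s = IndeterminateString([{"a"}, {INF}])
        t = IndeterminateString([{INF}, {"a"}])
        ts = index_mapping(s, t)
        assert ts.sets == ((), (1,))

    def test_index_mapping_validation(self):
        with pytest.raises(ValueError):
            IndexMapping([(0,)], source_len=2)
        with pytest.raises(ValueError):
            IndexMapping([(3,)], source_len=2)
        with pytest.raises(ValueError):
            IndexMapping([(1,)], source_len=1, provenance=("g1", "g2"))

    def test_pos_table(self):
        ts = IndexMapping([(1, 3), (), (1,), (2,)], source_len=3)
        assert ts.pos_table() == {1: [1, 3], 2: [4], 3: [1]}

    def test_i_reduced(self):
        ts = IndexMapping([(1, 3), (2,), ()], source_len=3)
        assert i_reduced(ts, 1) == (1, 2, INF)
        assert i_reduced(ts, 2) == (3, 2, INF)
        assert i_reduced(ts, 3) == (3, INF, INF)
        with pytest.raises(ValueError):
            ts.i_reduced(0)
        with pytest.raises(ValueError):
            ts.i_reduced(4)

    def test_min_rank_distance(self):
        tsi = (1, 3, 2, INF, 1)
        assert min_rank_distance(tsi, 1, 1) == 1
        assert min_rank_distance(tsi, 1, 3) == 3
        assert min_rank_distance(tsi, 3, 3) == 2
        assert min_rank_distance(tsi, 3, 5) == INF  # INF-absorbing
        with pytest.raises(IndexError):
            min_rank_distance(tsi, 0, 2)


# ---------------------------------------------------------------------------
# the index-mapping reduction preserves all pair predicates
# ---------------------------------------------------------------------------


class TestReductionEquivalence:
    def test_predicates_transfer_to_index_mapping(self):
        """weak status, indel counts and mutual closedness are identical on
        (S, T) and (I_S, T_S), interval for interval."""
        rng = random.Random(42)
        for rep in range(60):
            cfg = GenConfig(
                seed=rng.randint(0, 10**6),
                n=rng.randint(2, 20),
                m=rng.randint(2, 20),
                alphabet_size=rng.randint(2, 8),
                disjoint_alphabets=(rep % 17 == 5),
            )
            s, t = random_indeterminate_pair(cfg)
            direct = classify_all(s, t)
            mapped = classify_all(index_string(len(s)), index_mapping(s, t).to_string())
            assert np.array_equal(direct.s_intervals, mapped.s_intervals)
            assert np.array_equal(direct.t_intervals, mapped.t_intervals)
            assert np.array_equal(direct.indels, mapped.indels)
            assert np.array_equal(direct.weak, mapped.weak)
            assert np.array_equal(direct.mutually_closed, mapped.mutually_closed)
            assert np.array_equal(direct.nonempty_common, mapped.nonempty_common)

    def test_ordinary_strings_weak_iff_intersecting_everywhere(self):
        """On ordinary strings a pair is weak iff every position's character
        lies in the common set (spelled out per definition)."""
        rng = random.Random(9)
        for _ in range(20):
            cfg = GenConfig(
                seed=rng.randint(0, 10**6), n=9, m=9, alphabet_size=4, set_size_max=1
            )
            s, t = random_indeterminate_pair(cfg)
            assert s.is_ordinary() and t.is_ordinary()
            for _ in range(30):
                a = Interval(*sorted(rng.sample(range(1, len(s) + 1), 2)))
                b = Interval(*sorted(rng.sample(range(1, len(t) + 1), 2)))
                c = s.character_set(a.lo, a.hi) & t.character_set(b.lo, b.hi)
                expected = all(
                    next(iter(s.at(x))) in c for x in a.positions()
                ) and all(next(iter(t.at(y))) in c for y in b.positions())
                assert classify_pair(s, t, a, b).weak == expected


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

_position = st.sets(st.sampled_from("abcd"), min_size=1, max_size=3)
_string = st.lists(_position, min_size=1, max_size=8).map(IndeterminateString)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_string)
def test_cardinality_is_sum_of_set_sizes(s):
    assert s.cardinality() == sum(len(s.at(p)) for p in range(1, len(s) + 1))
    assert s.character_set() == s.alphabet()


@settings(derandomize=True, max_examples=60, deadline=None)
@given(_string, _string)
def test_index_mapping_is_intersection_table(s, t):
    ts = index_mapping(s, t)
    assert len(ts) == len(t) and ts.source_len == len(s)
    for y in range(1, len(t) + 1):
        expected = tuple(
            x for x in range(1, len(s) + 1) if s.at(x) & t.at(y)
        )
        assert ts.at(y) == expected


@settings(derandomize=True, max_examples=40, deadline=None)
@given(_string, _string, st.integers(min_value=1, max_value=8))
def test_i_reduced_matches_definition(s, t, i):
    ts = index_mapping(s, t)
    i = min(i, ts.source_len)
    red = ts.i_reduced(i)
    for y in range(1, len(ts) + 1):
        geq = [c for c in ts.at(y) if c >= i]
        assert red[y - 1] == (min(geq) if geq else INF)
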