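"""String and record distances, the banded bounded edit distance, budgets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linkclust.distances import (
    INCOMPARABLE,
    OVER,
    bounded_edit_distance,
    edit_distance,
    name_distance,
    nickname_distance,
    pair_threshold,
    phonetic_distance,
    record_distance,
    record_distance_bounded,
    reversal_distance,
    truncation_distance,
)
from linkclust.core_model import NicknameTable
from linkclust.metaphone import metaphone_encode

from .conftest import make_record, make_spec, oracle_edit_distance, random_instance

short_strings = st.text(alphabet="abcde", max_size=12)


class TestEditDistance:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ("abc", "abc", 0),
            ("", "abcd", 4),
            ("kitten", "sitting", 3),  # classic: 2 exchanges + 1 insert
            ("a", "", 1),
            ("abcd", "abdc", 2),
        ],
    )
    def test_known_values(self, s1, s2, expected):
        assert edit_distance(s1, s2) == expected
        assert oracle_edit_distance(s1, s2) == expected

    @settings(derandomize=True, max_examples=300)
    @given(short_strings, short_strings)
    def test_matches_recursion_oracle(self, s1, s2):
        assert edit_distance(s1, s2) == oracle_edit_distance(s1, s2)

    @settings(derandomize=True, max_examples=200)
    @given(short_strings, short_strings, short_strings)
    def test_metric_axioms(self, a, b, c):
        assert edit_distance(a, a) == 0
        assert edit_distance(a, b) == edit_distance(b, a)
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)

    @settings(derandomize=True, max_examples=200)
    @given(short_strings, short_strings)
    def test_length_bounds(self, s1, s2):
        # lower bound: length difference; upper bound: longer length
        d = edit_distance(s1, s2)
        assert abs(len(s1) - len(s2)) <= d <= max(len(s1), len(s2), 0) or (
            not s1 and not s2 and d == 0
        )


class TestBoundedEditDistance:
    @pytest.mark.parametrize(
        "s1, s2, t, expected",
        [
            ("ab", "abcdef", 2, OVER),  # length difference 4 > 2: no DP needed
            ("abc", "abd", 1, 1),
            ("abc", "xyz", 1, OVER),  # true distance 3
            ("same", "same", 0, 0),
            ("", "", 0, 0),
            ("abc", "", 3, 3),
        ],
    )
    def test_examples(self, s1, s2, t, expected):
        assert bounded_edit_distance(s1, s2, t) == expected

    def test_exact_iff_within_bound_random(self):
        # the acceptance-scale version of this check lives in test_acceptance
        rng = np.random.default_rng(2024)
        alphabet = "abcde"
        for _ in range(2000):
            n1, n2 = rng.integers(0, 16, size=2)
            s1 = "".join(rng.choice(list(alphabet), size=n1))
            s2 = "".join(rng.choice(list(alphabet), size=n2))
            t = int(rng.integers(0, 7))
            d = oracle_edit_distance(s1, s2)
            got = bounded_edit_distance(s1, s2, t)
            assert got == (d if d <= t else OVER)

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError):
            bounded_edit_distance("a", "b", -1)


class TestNameDistances:
    def test_reversal(self):
        assert reversal_distance("john", "smith", "smith", "john") == 0
        assert reversal_distance("john", "smith", "john", "smith") == 0
        # straight: ed(ann,lee)+ed(lee,anne)=3+4=7; swapped: ed(ann,anne)+0=1
        assert reversal_distance("ann", "lee", "lee", "anne") == 1

    def test_nickname(self, nickname_table):
        assert nickname_distance("robert", "bob", nickname_table) == 0
        assert nickname_distance("robert", "bobb", nickname_table) == 1
        # absent names: reduces to the plain edit distance
        empty = NicknameTable()
        assert nickname_distance("maria", "mario", empty) == edit_distance("maria", "mario")

    def test_truncation(self):
        assert truncation_distance("christopher", "christina", 5) == 0
        assert truncation_distance("maria", "mario", 5) == 1
        assert truncation_distance("al", "albert", 5) == 3  # ed("al","alber")

    def test_name_distance_examples(self, nickname_table):
        spec = make_spec(mode="nded", nickname_table=nickname_table)
        assert name_distance("john", "smith", "john", "smith", spec) == 0
        assert name_distance("john", "smith", "smith", "john", spec) == 0  # swap
        assert name_distance("robert", "jones", "bob", "jones", spec) == 0  # nickname
        assert name_distance("christopher", "lee", "christina", "lee", spec) == 0  # truncation

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="abcd", max_size=8), st.text(alphabet="abcd", max_size=8),
           st.text(alphabet="abcd", max_size=8), st.text(alphabet="abcd", max_size=8))
    def test_name_distance_min_contract(self, f1, l1, f2, l2):
        """name distance is <= each of its four ingredient combinations."""
        spec = make_spec(mode="nded")
        nd = name_distance(f1, l1, f2, l2, spec)
        table, L = spec.nickname_table, spec.truncation_length
        assert nd <= edit_distance(f1, f2) + edit_distance(l1, l2)
        assert nd <= reversal_distance(f1, l1, f2, l2)
        assert nd <= nickname_distance(f1, f2, table) + edit_distance(l1, l2)
        assert nd <= truncation_distance(f1, f2, L) + truncation_distance(l1, l2, L)


class TestPhoneticDistance:
    def test_equal_codes_distance_zero(self):
        assert metaphone_encode("smith") == metaphone_encode("smyth")
        assert phonetic_distance("smith", "smyth") == 0
        assert phonetic_distance("smith", "smith") == 0

    def test_different_codes_use_code_edit_distance(self):
        c1, c2 = metaphone_encode("smith"), metaphone_encode("jones")
        assert c1 != c2
        assert phonetic_distance("smith", "jones") == edit_distance(c1, c2) > 0

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", max_size=10))
    def test_self_distance_zero(self, s):
        assert phonetic_distance(s, s) == 0


class TestPairThreshold:
    def test_constant_is_constant(self):
        spec = make_spec(kind="constant", value=30)
        r1 = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "jane", "jones", "19850505", "f", "12345")
        assert pair_threshold(r1, r2, spec) == 30.0

    def test_proportional_mean_base(self):
        spec = make_spec(kind="proportional", value=0.35)
        # totlen 20 on both sides -> 0.35 * 20 = 7
        r1 = make_record("a", "abcde", "fghij", "12345", "m", "6789")
        r2 = make_record("b", "abcde", "fghij", "12345", "m", "6789")
        assert sum(len(v) for v in r1.attributes.values()) == 20
        assert pair_threshold(r1, r2, spec) == pytest.approx(7.0)
        assert pair_threshold(r1, r2, spec, 0.0) == 0.0

    def test_symmetric(self):
        spec = make_spec(kind="proportional", value=0.2)
        r1 = make_record("a", "jo", "li", "19900101", "m", "06269")
        r2 = make_record("b", "joseph", "lindqvist", "19850505", "f", "12345")
        assert pair_threshold(r1, r2, spec) == pair_threshold(r2, r1, spec)


class TestRecordDistance:
    def test_identical_records_zero_any_mode(self, schema):
        r = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "john", "smith", "19900101", "m", "06269")
        for mode in ("ed_all", "ed_name", "rded", "nded", "pded", "pd_name"):
            assert record_distance(r, r2, make_spec(mode=mode)) == 0

    def test_additive_combination(self):
        # ed(john,jhn)=1 and ed(06269,06270)=2 sum to 3
        r1 = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "jhn", "smith", "19900101", "m", "06270")
        assert record_distance(r1, r2, make_spec(mode="ed_all")) == 1 + 2

    def test_rded_name_swap_free(self):
        r1 = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "smith", "john", "19900101", "m", "06269")
        assert record_distance(r1, r2, make_spec(mode="rded")) == 0
        assert record_distance(r1, r2, make_spec(mode="ed_all")) > 0

    def test_missing_attribute_excluded(self):
        r1 = make_record("a", "john", "smith", "", "m", "06269")
        r2 = make_record("b", "john", "smith", "19900101", "m", "06269")
        assert record_distance(r1, r2, make_spec(mode="ed_all")) == 0

    def test_incomparable_pair(self):
        r1 = make_record("a", first="john")
        r2 = make_record("b", dob="19900101")
        assert record_distance(r1, r2, make_spec(mode="ed_all")) is INCOMPARABLE

    def test_symmetry_random(self):
        records, _ = random_instance(5, 30)
        spec = make_spec(mode="nded")
        rng = np.random.default_rng(0)
        for _ in range(100):
            r1, r2 = rng.choice(len(records), size=2, replace=False)
            assert record_distance(records[r1], records[r2], spec) == record_distance(
                records[r2], records[r1], spec
            )


class TestRecordDistanceBounded:
    def test_identical_at_zero(self):
        r1 = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "john", "smith", "19900101", "m", "06269")
        assert record_distance_bounded(r1, r2, make_spec(), 0) == 0

    def test_two_edits_over_budget_one(self):
        r1 = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "jhnn", "smith", "19900101", "m", "06269")
        assert record_distance_bounded(r1, r2, make_spec(), 1) is OVER

    def test_proportional_budget_floor(self):
        r1 = make_record("a", "john", "smith", "19900101", "m", "06269")
        r2 = make_record("b", "johm", "smith", "19900101", "m", "06269")
        spec = make_spec(kind="proportional", value=0.1)
        t = pair_threshold(r1, r2, spec)
        d = record_distance(r1, r2, spec)
        got = record_distance_bounded(r1, r2, spec, t)
        assert got == (d if d <= math.floor(t) else OVER)

    @pytest.mark.parametrize("mode", ["ed_all", "rded", "nded", "pded"])
    def test_agrees_with_unbounded_random(self, mode):
        """Accept/reject must equal the unbounded comparison on random pairs."""
        records, _ = random_instance(11, 60)
        spec = make_spec(mode=mode)
        rng = np.random.default_rng(42)
        n = len(records)
        for _ in range(800):
            i, j = rng.choice(n, size=2, replace=False)
            t = int(rng.integers(0, 8))
            rd = record_distance(records[i], records[j], spec)
            got = record_distance_bounded(records[i], records[j], spec, t)
            if rd is INCOMPARABLE:
                assert got is INCOMPARABLE
            elif rd <= t:
                assert got == rd
            else:
                assert got is OVER

    def test_order_free_decision(self, schema):
        """The accept decision cannot depend on attribute comparison order."""
        from linkclust.core_model import AttributeSchema

        reordered = AttributeSchema(
            names=("zip", "gender", "dob", "first", "last"),
            roles={"first": "first_name", "last": "last_name"},
        )
        records, _ = random_instance(3, 40)
        s1 = make_spec(mode="ed_all", schema=schema)
        s2 = make_spec(mode="ed_all", schema=reordered)
        rng = np.random.default_rng(1)
        for _ in range(300):
            i, j = rng.choice(len(records), size=2, replace=False)
            t = int(rng.integers(0, 6))
            a = record_distance_bounded(records[i], records[j], s1, t)
            b = record_distance_bounded(records[i], records[j], s2, t)
            assert (a is OVER) == (b is OVER)
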