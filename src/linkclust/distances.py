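"""Attribute- and record-level distances for record integration.

The record distance RD(R1, R2) between two records is the sum of per-
attribute distances over their *common* non-missing attributes (unit-cost
Levenshtein distance by default).  Six comparison modes handle common data-
entry errors in person names:

``ed_all``
    edit distance on every common attribute.
``ed_name``
    edit distance on first and last name only.
``rded``
    reversal distance (straight vs. swapped first/last pairing) on the
    name pair, edit distance elsewhere.
``nded``
    name distance — min of edit, reversal, nickname and truncation
    distances — on the name pair, edit distance elsewhere.
``pded``
    phonetic (Metaphone-code) distance on each name, edit distance
    elsewhere.
``pd_name``
    phonetic distance on the names only.

Clustering accepts a pair when RD is at or below a threshold: a *constant*
threshold is an absolute error budget ``t``; a *proportional* threshold is
a fraction ``p`` of record length.  :func:`record_distance_bounded` is the
fast path: each string comparison runs a banded dynamic program restricted
to a ``2t+1`` strip around the diagonal, quits as soon as the running band
minimum exceeds the remaining budget (diagonal values are non-decreasing,
so no cell downstream can recover), and passes the leftover budget —
threshold minus distance already spent — to the next attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .core_model import AttributeSchema, DEFAULT_SCHEMA, InputError, NicknameTable, Record
from .metaphone import metaphone_encode

__all__ = [
    "OVER",
    "INCOMPARABLE",
    "BoundedDistance",
    "DistanceSpec",
    "edit_distance",
    "bounded_edit_distance",
    "reversal_distance",
    "nickname_distance",
    "truncation_distance",
    "name_distance",
    "phonetic_distance",
    "pair_threshold",
    "record_distance",
    "record_distance_bounded",
    "normalized_distance",
    "pair_accepted",
]


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: Result of a bounded comparison whose true distance exceeds the bound.
OVER = _Sentinel("OVER")
#: Record pair with zero common non-missing attributes; beyond any threshold.
INCOMPARABLE = _Sentinel("INCOMPARABLE")

BoundedDistance = Union[int, _Sentinel]

MODES = ("ed_all", "ed_name", "rded", "nded", "pded", "pd_name")
_PROPORTIONAL_BASES = ("mean", "min", "max", "sum")


@dataclass
class DistanceSpec:
    """Everything a record comparison needs: mode, threshold, schema, tables.

    ``threshold_value`` is an integer error budget ``t`` for the constant
    kind, or a fraction ``p`` in [0, 1] of the pair's base length for the
    proportional kind (base = ``proportional_base`` over the two records'
    summed compared-attribute lengths; ``mean`` keeps the threshold
    symmetric and bounded by the longer record).  ``truncation_length`` is
    the prefix length L of the truncation distance.  Nickname lookup
    applies to first names; set ``nickname_last_names`` to widen it.
    """

    mode: str = "ed_all"
    threshold_kind: str = "constant"
    threshold_value: float = 1
    truncation_length: int = 5
    nickname_table: NicknameTable = field(default_factory=NicknameTable)
    schema: AttributeSchema = DEFAULT_SCHEMA
    phonetic_encoder: str = "metaphone"
    proportional_base: str = "mean"
    nickname_last_names: bool = False

    def __post_init__(self) -> None:
        self.mode = self.mode.lower()
        if self.mode not in MODES:
            raise InputError(f"unknown distance mode {self.mode!r}")
        if self.threshold_kind not in ("constant", "proportional"):
            raise InputError(f"unknown threshold kind {self.threshold_kind!r}")
        if self.threshold_value < 0:
            raise InputError("threshold must be non-negative")
        if self.threshold_kind == "constant":
            if self.threshold_value != int(self.threshold_value):
                raise InputError("constant threshold must be an integer")
            self.threshold_value = int(self.threshold_value)
        elif not 0 <= self.threshold_value <= 1:
            raise InputError("proportional threshold must lie in [0, 1]")
        if self.truncation_length < 1:
            raise InputError("truncation_length must be >= 1")
        if self.proportional_base not in _PROPORTIONAL_BASES:
            raise InputError(f"proportional_base must be one of {_PROPORTIONAL_BASES}")
        if self.phonetic_encoder != "metaphone":
            raise InputError(f"unknown phonetic encoder {self.phonetic_encoder!r}")

    def encode(self, s: str) -> str:
        return metaphone_encode(s)


# --------------------------------------------------------------------------
# String distances
# --------------------------------------------------------------------------

def edit_distance(s1: str, s2: str) -> int:
    """Unit-cost Levenshtein distance (insert, delete, exchange each cost 1)."""
    if s1 == s2:
        return 0
    if len(s1) < len(s2):
        s1, s2 = s2, s1
    if not s2:
        return len(s1)
    prev = list(range(len(s2) + 1))
    for i, c1 in enumerate(s1, 1):
        cur = [i] + [0] * len(s2)
        for j, c2 in enumerate(s2, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (c1 != c2))
        prev = cur
    return prev[-1]


def bounded_edit_distance(s1: str, s2: str, t: int) -> BoundedDistance:
    """Edit distance if it is <= ``t``, else :data:`OVER`.

    Three-stage fast path: (1) the length difference is a lower bound on
    the distance, so a difference beyond ``t`` is OVER with no DP at all;
    (2) the DP touches only cells within band offset ``t`` of the main
    diagonal (a trace-back path with at most ``t`` indels cannot leave
    it); (3) diagonal values never decrease, so once every cell of the
    current row's band exceeds ``t`` the computation stops as OVER.
    """
    if t < 0:
        raise ValueError("bound t must be non-negative")
    t = int(t)
    n, m = len(s1), len(s2)
    if abs(n - m) > t:
        return OVER
    if s1 == s2:
        return 0
    if t == 0:
        return OVER
    cap = t + 1  # any value above t is equivalent; clamp to keep ints small
    lo_prev = 0
    prev = list(range(min(m, t) + 1))  # row 0: D[0][j] = j
    for i in range(1, n + 1):
        lo = max(0, i - t)
        hi = min(m, i + t)
        cur: list[int] = []
        best = cap
        for j in range(lo, hi + 1):
            if j == 0:
                v = i
            else:
                v = cap
                k = j - lo_prev  # index of column j in prev row's band
                if 0 <= k < len(prev):  # deletion from s1
                    v = prev[k] + 1
                if cur:  # insertion into s1 (left neighbour, same row)
                    v = min(v, cur[-1] + 1)
                if 0 <= k - 1 < len(prev):  # match / exchange
                    v = min(v, prev[k - 1] + (s1[i - 1] != s2[j - 1]))
            v = min(v, cap)
            cur.append(v)
            if v < best:
                best = v
        if best > t:
            return OVER
        prev, lo_prev = cur, lo
    d = prev[m - lo_prev]
    return d if d <= t else OVER


def reversal_distance(first1: str, last1: str, first2: str, last2: str) -> int:
    """Smaller of the straight and the first/last-swapped name pairing."""
    straight = edit_distance(first1, first2) + edit_distance(last1, last2)
    swapped = edit_distance(first1, last2) + edit_distance(last1, first2)
    return min(straight, swapped)


def nickname_distance(n1: str, n2: str, table: NicknameTable) -> int:
    """Smallest edit distance over the two names' nickname variant sets."""
    v1 = table.variants(n1)
    v2 = table.variants(n2)
    return min(edit_distance(a, b) for a in v1 for b in v2)


def truncation_distance(n1: str, n2: str, L: int) -> int:
    """Edit distance of the length-``L`` prefixes (whole string if shorter)."""
    if L < 1:
        raise ValueError("truncation length must be >= 1")
    return edit_distance(n1[:L], n2[:L])


def name_distance(
    first1: str, last1: str, first2: str, last2: str, spec: DistanceSpec
) -> int:
    """Smallest of the edit, reversal, nickname and truncation combinations.

    Combinations over the (first, last) pair: (a) straight edit sum,
    (b) swapped pairing (reversal), (c) nickname distance on the first
    names plus edit distance on the last names (both names if
    ``nickname_last_names``), (d) truncation distance on both names.
    """
    L = spec.truncation_length
    table = spec.nickname_table
    candidates = [
        reversal_distance(first1, last1, first2, last2),  # covers (a) and (b)
        nickname_distance(first1, first2, table) + (
            nickname_distance(last1, last2, table)
            if spec.nickname_last_names
            else edit_distance(last1, last2)
        ),
        truncation_distance(first1, first2, L) + truncation_distance(last1, last2, L),
    ]
    return min(candidates)


def phonetic_distance(a1: str, a2: str, spec: Optional[DistanceSpec] = None) -> int:
    """0 if the Metaphone codes match, else the edit distance of the codes."""
    encode = spec.encode if spec is not None else metaphone_encode
    c1, c2 = encode(a1), encode(a2)
    if c1 == c2:
        return 0
    return edit_distance(c1, c2)


# --------------------------------------------------------------------------
# Record-level comparison plan
# --------------------------------------------------------------------------

def _comparisons(r1: Record, r2: Record, spec: DistanceSpec):
    """Yield comparison tasks over the pair's common non-missing attributes.

    Tasks are ``("edit", v1, v2)``, ``("phonetic", v1, v2)`` or
    ``("name_pair", f1, l1, f2, l2)``; a missing-in-either attribute is
    excluded from the comparison (it is not a common attribute of the
    pair).  Name-pair modes fall back to per-name edit distance when any
    of the four name values is missing.
    """
    schema = spec.schema
    mode = spec.mode
    first_attr = schema.first_name
    last_attr = schema.last_name
    name_attrs = {first_attr, last_attr} - {None}
    names_only = mode in ("ed_name", "pd_name")
    pair_mode = mode in ("rded", "nded")

    if pair_mode and first_attr and last_attr:
        f1, l1 = r1.get(first_attr), r1.get(last_attr)
        f2, l2 = r2.get(first_attr), r2.get(last_attr)
        if f1 and l1 and f2 and l2:
            yield ("name_pair", f1, l1, f2, l2)
        else:
            for attr in (first_attr, last_attr):
                v1, v2 = r1.get(attr), r2.get(attr)
                if v1 and v2:
                    yield ("edit", v1, v2)
    for attr in schema.names:
        if attr in name_attrs:
            if pair_mode:
                continue
            v1, v2 = r1.get(attr), r2.get(attr)
            if v1 and v2:
                if mode in ("pded", "pd_name"):
                    yield ("phonetic", v1, v2)
                else:
                    yield ("edit", v1, v2)
        else:
            if names_only:
                continue
            v1, v2 = r1.get(attr), r2.get(attr)
            if v1 and v2:
                yield ("edit", v1, v2)


def _task_lengths(task) -> tuple[int, int]:
    if task[0] == "name_pair":
        _, f1, l1, f2, l2 = task
        return (len(f1) + len(l1), len(f2) + len(l2))
    _, v1, v2 = task
    return (len(v1), len(v2))


def _base_length(r1: Record, r2: Record, spec: DistanceSpec) -> float:
    """Base length for proportional thresholds: compared-value lengths combined."""
    tot1 = tot2 = 0
    for task in _comparisons(r1, r2, spec):
        a, b = _task_lengths(task)
        tot1 += a
        tot2 += b
    base = spec.proportional_base
    if base == "mean":
        return (tot1 + tot2) / 2
    if base == "min":
        return float(min(tot1, tot2))
    if base == "max":
        return float(max(tot1, tot2))
    return float(tot1 + tot2)


def pair_threshold(
    r1: Record, r2: Record, spec: DistanceSpec, value: Optional[float] = None
) -> float:
    """Error budget for this pair: ``t`` (constant) or ``p``·base (proportional)."""
    v = spec.threshold_value if value is None else value
    if spec.threshold_kind == "constant":
        return float(v)
    return v * _base_length(r1, r2, spec)


def _task_distance(task, spec: DistanceSpec) -> int:
    kind = task[0]
    if kind == "name_pair":
        _, f1, l1, f2, l2 = task
        if spec.mode == "rded":
            return reversal_distance(f1, l1, f2, l2)
        return name_distance(f1, l1, f2, l2, spec)
    if kind == "phonetic":
        return phonetic_distance(task[1], task[2], spec)
    return edit_distance(task[1], task[2])


def record_distance(r1: Record, r2: Record, spec: DistanceSpec) -> BoundedDistance:
    """RD(R1, R2): sum of per-attribute distances over common attributes.

    Returns :data:`INCOMPARABLE` when the pair has no common non-missing
    attribute; callers treat that as a distance above any threshold.
    """
    total = 0
    any_task = False
    for task in _comparisons(r1, r2, spec):
        any_task = True
        total += _task_distance(task, spec)
    if not any_task:
        return INCOMPARABLE
    return total


# --------------------------------------------------------------------------
# Bounded record distance with budget propagation
# --------------------------------------------------------------------------

def _bounded_sum2(a1: str, a2: str, b1: str, b2: str, budget: int) -> BoundedDistance:
    d1 = bounded_edit_distance(a1, a2, budget)
    if d1 is OVER:
        return OVER
    d2 = bounded_edit_distance(b1, b2, budget - d1)
    if d2 is OVER:
        return OVER
    return d1 + d2


def _bounded_nickname(n1: str, n2: str, table: NicknameTable, budget: int) -> BoundedDistance:
    best: BoundedDistance = OVER
    cap = budget
    for a in table.variants(n1):
        for b in table.variants(n2):
            d = bounded_edit_distance(a, b, cap)
            if d is not OVER:
                best = d if best is OVER else min(best, d)
                if best == 0:
                    return 0
                cap = best  # tighter bound for the remaining variants
    return best


def _bounded_task(task, spec: DistanceSpec, budget: int) -> BoundedDistance:
    kind = task[0]
    if kind == "edit":
        return bounded_edit_distance(task[1], task[2], budget)
    if kind == "phonetic":
        c1, c2 = spec.encode(task[1]), spec.encode(task[2])
        if c1 == c2:
            return 0
        return bounded_edit_distance(c1, c2, budget)
    _, f1, l1, f2, l2 = task
    candidates: list[BoundedDistance] = [
        _bounded_sum2(f1, f2, l1, l2, budget),  # straight pairing
        _bounded_sum2(f1, l2, l1, f2, budget),  # swapped pairing
    ]
    if spec.mode == "nded":
        table = spec.nickname_table
        dn = _bounded_nickname(f1, f2, table, budget)
        if dn is not OVER:
            dl = (
                _bounded_nickname(l1, l2, table, budget - dn)
                if spec.nickname_last_names
                else bounded_edit_distance(l1, l2, budget - dn)
            )
            candidates.append(OVER if dl is OVER else dn + dl)
        L = spec.truncation_length
        candidates.append(_bounded_sum2(f1[:L], f2[:L], l1[:L], l2[:L], budget))
    finite = [c for c in candidates if c is not OVER]
    return min(finite) if finite else OVER


def record_distance_bounded(
    r1: Record, r2: Record, spec: DistanceSpec, t: float
) -> BoundedDistance:
    """RD(R1, R2) if it is <= floor(t), else :data:`OVER`.

    Attributes are compared in schema order; each comparison receives the
    budget still unspent (the threshold minus the distance already used)
    and the whole computation stops at the first OVER.  The accept/reject
    outcome equals ``record_distance(r1, r2, spec) <= floor(t)`` — the sum
    is order-free — but failing pairs are detected early.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    budget = math.floor(t)
    used = 0
    any_task = False
    for task in _comparisons(r1, r2, spec):
        any_task = True
        d = _bounded_task(task, spec, budget - used)
        if d is OVER:
            return OVER
        used += d
    if not any_task:
        return INCOMPARABLE
    return used


def pair_accepted(
    r1: Record, r2: Record, spec: DistanceSpec, threshold: Optional[float] = None
) -> bool:
    """True when RD(R1, R2) is within the pair's threshold."""
    t = pair_threshold(r1, r2, spec, threshold)
    return isinstance(record_distance_bounded(r1, r2, spec, t), int)


def normalized_distance(r1: Record, r2: Record, spec: DistanceSpec) -> float:
    """Distance on the scale the threshold lives on.

    Constant mode: the raw integer record distance.  Proportional mode:
    record distance divided by the pair's base length, so a single cut
    level ``p`` exists for the dendrogram.  Incomparable pairs map to
    ``inf``.
    """
    rd = record_distance(r1, r2, spec)
    if rd is INCOMPARABLE:
        return math.inf
    if spec.threshold_kind == "constant":
        return float(rd)
    base = _base_length(r1, r2, spec)
    if base == 0:
        return 0.0 if rd == 0 else math.inf
    return rd / base
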