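"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written against the mathematical
definitions, independent of the package implementations they check:
a memoized-recursion Levenshtein distance, a networkx connected-components
reference for threshold-graph clustering, and scipy's single-linkage
dendrogram.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx
import pytest

from linkclust.core_model import AttributeSchema, NicknameTable, Record
from linkclust.distances import DistanceSpec, INCOMPARABLE, pair_threshold, record_distance
from linkclust.synthetic_data import GeneratorParams, default_nickname_table, generate_datasets


def oracle_edit_distance(s1: str, s2: str) -> int:
    """Levenshtein distance by memoized recursion over all edit scripts."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (s1[i - 1] != s2[j - 1]),
        )

    return d(len(s1), len(s2))


def threshold_graph_components(records, spec, threshold):
    """Connected components of the explicit threshold graph (networkx oracle).

    Edges come from the *unbounded* record distance compared against the
    pair threshold, with no banding, budgets or blocking involved.
    """
    g = nx.Graph()
    g.add_nodes_from(r.record_id for r in records)
    for i, r1 in enumerate(records):
        for r2 in records[i + 1 :]:
            rd = record_distance(r1, r2, spec)
            if rd is INCOMPARABLE:
                continue
            if rd <= pair_threshold(r1, r2, spec, threshold):
                g.add_edge(r1.record_id, r2.record_id)
    return frozenset(frozenset(c) for c in nx.connected_components(g))


@pytest.fixture
def schema() -> AttributeSchema:
    return AttributeSchema(
        names=("first", "last", "dob", "gender", "zip"),
        roles={"first": "first_name", "last": "last_name"},
    )


@pytest.fixture
def nickname_table() -> NicknameTable:
    return NicknameTable([("robert", "bob"), ("william", "bill"), ("elizabeth", "liz")])


def make_record(rid: str, first="", last="", dob="", gender="", zip_="", entity=None) -> Record:
    return Record(
        record_id=rid,
        dataset_id="d0",
        attributes={"first": first, "last": last, "dob": dob, "gender": gender, "zip": zip_},
        entity_id=entity,
    )


def make_spec(mode="ed_all", kind="constant", value=1, **kw) -> DistanceSpec:
    kw.setdefault("nickname_table", default_nickname_table())
    return DistanceSpec(mode=mode, threshold_kind=kind, threshold_value=value, **kw)


def random_instance(seed: int, n_entities: int, **params_kw):
    """A seeded synthetic instance: (records, truth)."""
    params = GeneratorParams(n_entities=n_entities, seed=seed, **params_kw)
    return generate_datasets(params)
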