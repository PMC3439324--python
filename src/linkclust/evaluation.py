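"""Ground-truth evaluation: accuracy, completeness, Type I-IV analysis.

With ``N`` output clusters, ``C`` *correct* clusters (a cluster is correct
when it contains all the records of exactly one entity and nothing else)
and ``N*`` distinct entities:

* accuracy   = C / N      — how trustworthy an output cluster is;
* completeness = C / N*   — how many entities were recovered exactly.

The four-category analysis assigns every cluster exactly one type:

* Type I   — one entity's records, all of them (a correct cluster);
* Type II  — one entity's records, but not all of them;
* Type III — all records of some entity plus records of others;
* Type IV  — everything else (the true errors).

Type fractions are computed over ``N``, so they sum to one and the Type I
fraction equals the accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .core_model import Clustering, InputError

__all__ = [
    "EvaluationReport",
    "accuracy",
    "completeness",
    "four_category",
    "evaluate",
]

logger = logging.getLogger(__name__)

_TYPES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class EvaluationReport:
    """Cluster-level evaluation summary."""

    n_clusters: int
    n_correct: int
    n_entities: int
    accuracy: float
    completeness: float
    type_fractions: Mapping[str, float] = field(default_factory=dict)
    n_excluded_records: int = 0

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "n_correct": self.n_correct,
            "n_entities": self.n_entities,
            "accuracy": self.accuracy,
            "completeness": self.completeness,
            "type_fractions": dict(self.type_fractions),
            "n_excluded_records": self.n_excluded_records,
        }


def _restrict(clustering: Clustering, truth: Mapping[str, str]):
    """Drop records without ground truth (with a logged count).

    Returns (clusters as list of id-sets, entity -> full record set).
    """
    excluded = [rid for rid in clustering.record_ids if rid not in truth]
    if excluded:
        logger.info("evaluation: excluding %d records without ground truth", len(excluded))
    ex = set(excluded)
    clusters = []
    for members in clustering.values():
        kept = members - ex
        if kept:
            clusters.append(kept)
    entity_records: dict[str, set[str]] = {}
    for rid in clustering.record_ids:
        if rid in truth:
            entity_records.setdefault(truth[rid], set()).add(rid)
    if not clusters:
        raise InputError("evaluation undefined: no clusters with ground truth")
    return clusters, entity_records, len(excluded)


def _classify(members, truth, entity_records) -> str:
    entities = {truth[rid] for rid in members}
    if len(entities) == 1:
        ent = next(iter(entities))
        return "I" if members == entity_records[ent] else "II"
    if any(entity_records[e] <= members for e in entities):
        return "III"
    return "IV"


def evaluate(clustering: Clustering, truth: Mapping[str, str]) -> EvaluationReport:
    """Full report: N, C, N*, accuracy, completeness and type fractions."""
    clusters, entity_records, n_excluded = _restrict(clustering, truth)
    n = len(clusters)
    counts = {t: 0 for t in _TYPES}
    for members in clusters:
        counts[_classify(members, truth, entity_records)] += 1
    c = counts["I"]
    n_star = len(entity_records)
    return EvaluationReport(
        n_clusters=n,
        n_correct=c,
        n_entities=n_star,
        accuracy=c / n,
        completeness=c / n_star,
        type_fractions={t: counts[t] / n for t in _TYPES},
        n_excluded_records=n_excluded,
    )


def accuracy(clustering: Clustering, truth: Mapping[str, str]) -> float:
    """C/N: fraction of output clusters that are exactly one whole entity."""
    return evaluate(clustering, truth).accuracy


def completeness(clustering: Clustering, truth: Mapping[str, str]) -> float:
    """C/N*: fraction of entities recovered as a correct cluster."""
    return evaluate(clustering, truth).completeness


def four_category(clustering: Clustering, truth: Mapping[str, str]) -> dict[str, float]:
    """Type I-IV fractions of the N output clusters (they sum to one)."""
    return dict(evaluate(clustering, truth).type_fractions)
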