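"""Non-blocking integration algorithms: BIA, PCD and IDS.

All three produce the same partition of the input records — a single-
linkage dendrogram cut at level ``t`` equals the connected components of
the graph whose edges are the record pairs with distance <= ``t`` — but
they trade time and memory differently:

* **BIA** builds the full dendrogram and cuts it (O(n^2) space; the
  dendrogram can then be re-cut at any level for free).
* **PCD** runs the same agglomeration but stops at the first merge above
  the threshold, never constructing the tree above the cut.
* **IDS** drops the tree entirely: it grows one cluster at a time by
  breadth-first neighbor search with the bounded record distance, using
  O(n) memory and no pairwise matrix.

Distances are compared on the *normalized* scale (raw record distance for
constant thresholds, distance divided by the pair's base length for
proportional ones) so that a single cut level exists in both regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core_model import Clustering, InputError, Record
from .distances import DistanceSpec, normalized_distance, pair_accepted

__all__ = [
    "Dendrogram",
    "DendrogramNode",
    "build_dendrogram",
    "cut_dendrogram",
    "bia_cluster",
    "pcd_cluster",
    "ids_cluster",
]


@dataclass(frozen=True)
class DendrogramNode:
    """A dendrogram node: leaf (record, level 0) or merge of two children."""

    level: float
    members: frozenset[str]
    record_id: Optional[str] = None
    left: Optional["DendrogramNode"] = None
    right: Optional["DendrogramNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.record_id is not None


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree from single-linkage agglomeration; one root."""

    root: DendrogramNode

    @property
    def n_leaves(self) -> int:
        return len(self.root.members)

    def cut(self, threshold: float) -> Clustering:
        return cut_dendrogram(self, threshold)

    def to_newick(self) -> str:
        """Nested-parenthesis dump with merge levels as node annotations."""
        out: list[str] = []
        # explicit stack; merge chains can exceed the recursion limit
        stack: list[tuple[DendrogramNode, int]] = [(self.root, 0)]
        while stack:
            node, phase = stack.pop()
            if node.is_leaf:
                out.append(node.record_id)
            elif phase == 0:
                out.append("(")
                stack.append((node, 1))
                stack.append((node.left, 0))
            elif phase == 1:
                out.append(",")
                stack.append((node, 2))
                stack.append((node.right, 0))
            else:
                lvl = node.level
                out.append(f"){lvl:g}" if math.isfinite(lvl) else ")inf")
        return "".join(out) + ";"


# --------------------------------------------------------------------------
# Single-linkage agglomeration engine
# --------------------------------------------------------------------------

def _single_linkage(
    records: Sequence[Record], spec: DistanceSpec, stop: Optional[float]
) -> list[DendrogramNode]:
    """Agglomerate with the single-linkage update d(new,k)=min(d(i,k),d(j,k)).

    With ``stop`` set, merging halts at the first inter-cluster distance
    strictly above it (PCD); with ``stop=None`` merging continues to a
    single root (BIA).  Deterministic tie-break: among minimum-distance
    pairs, merge the one whose (smaller cluster id, larger cluster id) is
    lexicographically least; a merged cluster inherits its least member
    record_id as id, so the rule is independent of input order.

    Returns the forest of root nodes.
    """
    if not records:
        raise InputError("cannot cluster an empty record set")
    ids = sorted(r.record_id for r in records)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate record ids in clustering input")
    by_id = {r.record_id: r for r in records}
    nodes: dict[str, DendrogramNode] = {
        rid: DendrogramNode(level=0.0, members=frozenset([rid]), record_id=rid)
        for rid in ids
    }
    if len(ids) == 1:
        return [nodes[ids[0]]]

    # Pairwise normalized distances between active clusters.
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        ra = by_id[a]
        for b in ids[i + 1 :]:
            dist[(a, b)] = normalized_distance(ra, by_id[b], spec)

    def pairkey(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    # Nearest neighbor per cluster as (distance, small id, large id).
    # Under single linkage a merge never increases any cross distance, so
    # when a cluster's nearest neighbor gets merged the new cluster simply
    # takes its place.
    active = set(ids)
    nn: dict[str, tuple[float, str, str]] = {}

    def recompute_nn(c: str) -> None:
        best = None
        for k in active:
            if k == c:
                continue
            cand = (dist[pairkey(c, k)], *pairkey(c, k))
            if best is None or cand < best:
                best = cand
        nn[c] = best

    for c in active:
        recompute_nn(c)

    while len(active) > 1:
        d, a, b = min(nn[c] for c in active)
        if stop is not None and d > stop:
            break
        new_id = a  # a < b and ids are least members, so a is the least member
        merged = DendrogramNode(
            level=d,
            members=nodes[a].members | nodes[b].members,
            left=nodes[a],
            right=nodes[b],
        )
        active.discard(a)
        active.discard(b)
        for k in active:
            dist[pairkey(new_id, k)] = min(dist[pairkey(a, k)], dist[pairkey(b, k)])
        nodes[new_id] = merged
        nn.pop(b, None)
        active.add(new_id)
        recompute_nn(new_id)
        for k in active:
            if k == new_id:
                continue
            dk, pa, pb = nn[k]
            if pa in (a, b) or pb in (a, b):
                # the old neighbor is gone; the merged cluster is at least
                # as close as it was, and no other distance changed
                cand = (dist[pairkey(k, new_id)], *pairkey(k, new_id))
                nn[k] = cand
    return [nodes[c] for c in sorted(active)]


def build_dendrogram(records: Sequence[Record], spec: DistanceSpec) -> Dendrogram:
    """Full single-linkage dendrogram over the records (BIA step 1)."""
    roots = _single_linkage(records, spec, stop=None)
    root = roots[0]
    if len(roots) > 1:  # pragma: no cover - merging runs to a single root
        for other in roots[1:]:
            root = DendrogramNode(
                level=math.inf, members=root.members | other.members,
                left=root, right=other,
            )
    return Dendrogram(root=root)


def cut_dendrogram(dend: Dendrogram, threshold: float) -> Clustering:
    """Maximal subtrees at merge level <= ``threshold`` (BIA step 2)."""
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    groups: list[frozenset[str]] = []
    stack = [dend.root]
    while stack:
        node = stack.pop()
        if node.level <= threshold:
            groups.append(node.members)
        else:
            stack.append(node.left)
            stack.append(node.right)
    return Clustering.from_groups(groups)


def bia_cluster(
    records: Sequence[Record], spec: DistanceSpec, threshold: float
) -> Clustering:
    """Basic integration algorithm: build the dendrogram, cut, output."""
    return cut_dendrogram(build_dendrogram(records, spec), threshold)


def pcd_cluster(
    records: Sequence[Record], spec: DistanceSpec, threshold: float
) -> Clustering:
    """Partial construction of the dendrogram: stop merging above ``threshold``.

    Produces the identical partition to ``bia_cluster`` while never
    building the part of the tree above the cut.
    """
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    roots = _single_linkage(records, spec, stop=threshold)
    return Clustering.from_groups(root.members for root in roots)


def ids_cluster(
    records: Sequence[Record], spec: DistanceSpec, threshold: float
) -> Clustering:
    """Ignore the dendrogram structure: grow clusters by neighbor search.

    Repeatedly seeds a cluster with the smallest unassigned record id and
    adds every remaining record within the threshold of any cluster
    member, transitively, until no new neighbor is found; the cluster is
    output and its records removed.  The result is exactly the connected
    components of the threshold graph.  No pairwise matrix is held — the
    bounded record distance with budget propagation decides each pair on
    the fly — so memory stays O(n).
    """
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    remaining = sorted(records, key=lambda r: r.record_id)
    groups: list[set[str]] = []
    while remaining:
        seed = remaining.pop(0)
        cluster = {seed.record_id}
        frontier = [seed]
        while frontier:
            r = frontier.pop()
            still: list[Record] = []
            for other in remaining:
                if pair_accepted(r, other, spec, threshold):
                    cluster.add(other.record_id)
                    frontier.append(other)
                else:
                    still.append(other)
            remaining = still
        groups.append(cluster)
    return Clustering.from_groups(groups)
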