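"""Two-phase algorithm (TPA): last-name l-mer blocking + per-block IDS.

Phase one indexes every record under each distinct length-``l`` substring
(l-mer) of its normalized last name — e.g. ``rueckl`` with ``l=3`` lands in
the four blocks ``rue``, ``uec``, ``eck``, ``ckl`` — so expensive record
comparisons happen only between records sharing a block.  Over a 26-letter
name alphabet there are ``26**l`` possible keys (17,576 for 3-mers).
Phase two runs IDS inside each block and merges clusters that share a
record, since one record may belong to multiple blocks.

The trade-off is deliberate: records whose last names share no l-mer are
never compared, so the TPA partition refines (or equals) the IDS
partition; same-entity pairs whose last names have no common l-mer are the
accuracy price paid for the speedup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_model import Clustering, Record
from .clustering import ids_cluster
from .distances import DistanceSpec

__all__ = ["BlockIndex", "lmer_blocks", "merge_overlapping_clusters", "tpa_cluster"]

#: Key prefix for records with an empty last name; each sits alone in a
#: pseudo-block and is compared only against itself.
_NOKEY_PREFIX = "\x00nokey:"


@dataclass(frozen=True)
class BlockIndex:
    """l-mer key -> record-id set, plus the l-mer length used."""

    blocks: Mapping[str, frozenset[str]]
    l: int

    @property
    def b(self) -> int:
        """Number of non-empty blocks."""
        return len(self.blocks)

    def keys_for(self, last_name: str) -> frozenset[str]:
        """Distinct block keys a normalized last name is indexed under."""
        if len(last_name) >= self.l:
            return frozenset(
                last_name[i : i + self.l] for i in range(len(last_name) - self.l + 1)
            )
        return frozenset([last_name]) if last_name else frozenset()


def lmer_blocks(records: Sequence[Record], l: int, spec: DistanceSpec) -> BlockIndex:
    """Index each record under every distinct l-mer of its last name.

    A last name shorter than ``l`` is indexed under the whole name
    (skipping such records would orphan them silently); a record with no
    last name gets a private pseudo-block.
    """
    if l < 1:
        raise ValueError("l-mer length must be >= 1")
    last_attr = spec.schema.last_name
    blocks: dict[str, set[str]] = {}
    for r in records:
        name = r.get(last_attr) if last_attr else ""
        if not name:
            blocks.setdefault(_NOKEY_PREFIX + r.record_id, set()).add(r.record_id)
            continue
        if len(name) >= l:
            keys = {name[i : i + l] for i in range(len(name) - l + 1)}
        else:
            keys = {name}
        for key in keys:
            blocks.setdefault(key, set()).add(r.record_id)
    return BlockIndex(
        blocks={k: frozenset(v) for k, v in blocks.items()}, l=l
    )


def merge_overlapping_clusters(clusterings: Iterable[Clustering]) -> Clustering:
    """Union clusters (possibly from different blocks) that share a record.

    Union-find over record ids: each input cluster unions its members, so
    the output components are exactly the connected components of the
    cluster-record overlap graph.  The result partitions the union of all
    input records.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            if ry < rx:  # keep the least id as representative
                rx, ry = ry, rx
            parent[ry] = rx

    for clustering in clusterings:
        for members in clustering.values():
            first = None
            for rid in members:
                parent.setdefault(rid, rid)
                if first is None:
                    first = rid
                else:
                    union(first, rid)
    groups: dict[str, set[str]] = {}
    for rid in parent:
        groups.setdefault(find(rid), set()).add(rid)
    return Clustering.from_groups(groups.values())


def tpa_cluster(
    records: Sequence[Record], spec: DistanceSpec, threshold: float, l: int = 3
) -> Clustering:
    """Two-phase integration: block by last-name l-mers, IDS per block, merge.

    The per-block runs reuse the global distance spec and threshold
    unchanged; duplicate work on records shared between blocks is accepted
    and deduplicated at the merge step.  Blocks are processed in sorted
    key order for reproducible logs, though the output partition is
    order-invariant.
    """
    if not records:
        return Clustering({})
    index = lmer_blocks(records, l, spec)
    by_id = {r.record_id: r for r in records}
    block_results: list[Clustering] = []
    for key in sorted(index.blocks):
        block_records = [by_id[rid] for rid in sorted(index.blocks[key])]
        block_results.append(ids_cluster(block_records, spec, threshold))
    merged = merge_overlapping_clusters(block_results)
    merged.check_partition_of(by_id)
    return merged
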