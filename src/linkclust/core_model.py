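"""Domain types and I/O for multi-source record integration.

The central objects are :class:`Record` (one person-record from one source
dataset), :class:`AttributeSchema` (which attributes exist and which of them
play the first-name / last-name roles), :class:`NicknameTable` (symmetric
name-variant lookup) and :class:`Clustering` (a partition of record ids —
the output of every integration algorithm).

All distance computations assume *normalized* values: lowercase, trimmed,
name values restricted to ``a-z`` (so names live on a 26-letter alphabet)
and date-like values canonicalized to ``YYYYMMDD`` digit strings.
"""

from __future__ import annotations

import csv
import json
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "Record",
    "AttributeSchema",
    "NicknameTable",
    "Clustering",
    "InputError",
    "normalize_value",
    "normalize_record",
    "read_records_csv",
    "write_clusters_csv",
    "read_clusters_csv",
    "read_truth_csv",
    "load_config",
    "IntegrationConfig",
    "DEFAULT_SCHEMA",
]


class InputError(ValueError):
    """Raised for malformed input files or invalid configuration."""


# --------------------------------------------------------------------------
# Schema and records
# --------------------------------------------------------------------------

_ROLES = ("first_name", "last_name", "other")


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered attribute list with role tags.

    The order of ``names`` is the comparison order used by the bounded
    record distance; it is fixed and deterministic.  At most one attribute
    may carry the ``first_name`` role and at most one the ``last_name``
    role.
    """

    names: tuple[str, ...]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        roles = dict(self.roles)
        for name, role in roles.items():
            if name not in self.names:
                raise InputError(f"role for unknown attribute {name!r}")
            if role not in _ROLES:
                raise InputError(f"unknown role {role!r} for attribute {name!r}")
        for role in ("first_name", "last_name"):
            if sum(1 for r in roles.values() if r == role) > 1:
                raise InputError(f"more than one attribute tagged {role}")
        object.__setattr__(self, "roles", roles)

    def role(self, name: str) -> str:
        return self.roles.get(name, "other")

    @property
    def first_name(self) -> Optional[str]:
        for name in self.names:
            if self.roles.get(name) == "first_name":
                return name
        return None

    @property
    def last_name(self) -> Optional[str]:
        for name in self.names:
            if self.roles.get(name) == "last_name":
                return name
        return None

    @classmethod
    def infer(cls, columns: Iterable[str]) -> "AttributeSchema":
        """Infer a schema from CSV column names.

        Columns named ``record_id``/``dataset_id``/``entity_id`` are
        bookkeeping, not attributes.  A column whose name starts with
        ``first`` is tagged first_name, one starting with ``last`` is
        tagged last_name.
        """
        names = [c for c in columns if c not in ("record_id", "dataset_id", "entity_id")]
        roles: dict[str, str] = {}
        for c in names:
            lc = c.lower()
            if lc.startswith("first") and "first_name" not in roles.values():
                roles[c] = "first_name"
            elif lc.startswith("last") and "last_name" not in roles.values():
                roles[c] = "last_name"
        return cls(tuple(names), roles)


DEFAULT_SCHEMA = AttributeSchema(
    names=("first", "last", "dob", "gender", "zip"),
    roles={"first": "first_name", "last": "last_name"},
)


@dataclass(frozen=True)
class Record:
    """One person-record: unique id, source dataset, attribute values.

    Empty attribute values mean *missing*; a missing attribute is excluded
    from the common attributes compared between two records.  ``entity_id``
    is ground truth, used only for evaluation and synthetic data.
    """

    record_id: str
    dataset_id: str = ""
    attributes: Mapping[str, str] = field(default_factory=dict)
    entity_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise InputError("record without a record_id")
        object.__setattr__(self, "attributes", dict(self.attributes))

    def get(self, name: str) -> str:
        return self.attributes.get(name, "")


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

_DATE_PATTERNS = (
    re.compile(r"^(\d{4})[-/.](\d{1,2})[-/.](\d{1,2})$"),  # 1990-01-02
    re.compile(r"^(\d{4})(\d{2})(\d{2})$"),  # 19900102
)
_DATE_PATTERNS_MDY = (re.compile(r"^(\d{1,2})[-/.](\d{1,2})[-/.](\d{4})$"),)  # 01/02/1990

_NON_ALPHA = re.compile(r"[^a-z]")
_NON_ALNUM = re.compile(r"[^a-z0-9]")


def _canonical_date(value: str) -> Optional[str]:
    for pat in _DATE_PATTERNS:
        m = pat.match(value)
        if m:
            y, mo, d = m.groups()
            if 1 <= int(mo) <= 12 and 1 <= int(d) <= 31:
                return f"{int(y):04d}{int(mo):02d}{int(d):02d}"
    for pat in _DATE_PATTERNS_MDY:
        m = pat.match(value)
        if m:
            mo, d, y = m.groups()
            if 1 <= int(mo) <= 12 and 1 <= int(d) <= 31:
                return f"{int(y):04d}{int(mo):02d}{int(d):02d}"
    return None


def normalize_value(value: str, role: str = "other") -> str:
    """Normalize a raw attribute value.

    Lowercase and trim; name-role values keep only ``a-z``; other values
    are canonicalized to ``YYYYMMDD`` when they parse as a date, otherwise
    reduced to lowercase letters and digits.
    """
    v = value.strip().lower()
    if role in ("first_name", "last_name"):
        return _NON_ALPHA.sub("", v)
    date = _canonical_date(v)
    if date is not None:
        return date
    return _NON_ALNUM.sub("", v)


def normalize_record(raw: Record, schema: AttributeSchema) -> Record:
    """Return a copy of ``raw`` with all schema attributes normalized."""
    if not raw.record_id:
        raise InputError("record without a record_id")
    attrs = {name: normalize_value(raw.get(name), schema.role(name)) for name in schema.names}
    return Record(
        record_id=raw.record_id,
        dataset_id=raw.dataset_id,
        attributes=attrs,
        entity_id=raw.entity_id,
    )


# --------------------------------------------------------------------------
# Nickname table
# --------------------------------------------------------------------------

class NicknameTable:
    """Symmetric name-variant lookup.

    Built from (name, variant) pairs; the symmetric closure is applied on
    construction so ``y in variants(x)`` iff ``x in variants(y)``, and every
    name is a variant of itself.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        table: dict[str, set[str]] = {}
        for a, b in pairs:
            a = normalize_value(a, "first_name")
            b = normalize_value(b, "first_name")
            if not a or not b or a == b:
                continue
            table.setdefault(a, set()).add(b)
            table.setdefault(b, set()).add(a)
        self._table = {k: frozenset(v) for k, v in table.items()}

    def variants(self, name: str) -> frozenset[str]:
        """All variants of ``name``, always including ``name`` itself."""
        return self._table.get(name, frozenset()) | {name}

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, name: str) -> bool:
        return name in self._table

    @classmethod
    def from_csv(cls, path: str | Path) -> "NicknameTable":
        """Load a two-column (name, variant) CSV; a header row is optional."""
        pairs: list[tuple[str, str]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row or len(row) < 2:
                    continue
                if i == 0 and row[0].strip().lower() in ("name", "nickname", "first"):
                    continue
                pairs.append((row[0], row[1]))
        return cls(pairs)


# --------------------------------------------------------------------------
# Clustering
# --------------------------------------------------------------------------

class Clustering(Mapping):
    """A partition of record ids into clusters (cluster_id -> id set).

    Disjointness is checked on construction; a violation is a hard error.
    Two clusterings are equal when they induce the same partition,
    regardless of cluster ids.
    """

    def __init__(self, clusters: Mapping[str, Iterable[str]]) -> None:
        self._clusters: dict[str, frozenset[str]] = {}
        seen: set[str] = set()
        for cid, members in clusters.items():
            mem = frozenset(members)
            if not mem:
                raise InputError(f"cluster {cid!r} is empty")
            overlap = seen & mem
            if overlap:
                raise InputError(
                    f"records in more than one cluster: {sorted(overlap)[:5]}"
                )
            seen |= mem
            self._clusters[cid] = mem

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "Clustering":
        """Build a clustering with each cluster id set to its least member."""
        return cls({min(g): set(g) for g in (set(g) for g in groups) if g})

    def __getitem__(self, cid: str) -> frozenset[str]:
        return self._clusters[cid]

    def __iter__(self):
        return iter(self._clusters)

    def __len__(self) -> int:
        return len(self._clusters)

    @property
    def record_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for mem in self._clusters.values():
            out |= mem
        return frozenset(out)

    def as_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(self._clusters.values())

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Clustering):
            return self.as_sets() == other.as_sets()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.as_sets())

    def check_partition_of(self, record_ids: Iterable[str]) -> None:
        """Assert this clustering partitions exactly ``record_ids``."""
        expected = set(record_ids)
        got = set(self.record_ids)
        if expected != got:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise InputError(f"not a partition: missing={missing} extra={extra}")

    def refines(self, other: "Clustering") -> bool:
        """True if every cluster here is a subset of some cluster of ``other``."""
        owner: dict[str, frozenset[str]] = {}
        for mem in other.values():
            for rid in mem:
                owner[rid] = mem
        for mem in self.values():
            first = owner.get(next(iter(mem)))
            if first is None or not mem <= first:
                return False
        return True


# --------------------------------------------------------------------------
# CSV / config I/O
# --------------------------------------------------------------------------

def read_records_csv(
    path: str | Path,
    schema: Optional[AttributeSchema] = None,
    dataset_id: Optional[str] = None,
) -> list[Record]:
    """Read and normalize one CSV of person records.

    The file must have a header containing ``record_id`` plus the schema
    attribute columns; optional ``dataset_id`` and ``entity_id`` columns are
    picked up when present.  ``dataset_id`` (argument) overrides the column.
    Row order is preserved; a duplicated record id is an error.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InputError(f"{path}: empty file (no header)")
        if "record_id" not in reader.fieldnames:
            raise InputError(f"{path}: missing required column 'record_id'")
        if schema is None:
            schema = AttributeSchema.infer(reader.fieldnames)
        missing_cols = [c for c in schema.names if c not in reader.fieldnames]
        if missing_cols:
            raise InputError(f"{path}: missing schema columns {missing_cols}")
        records: list[Record] = []
        seen: set[str] = set()
        for row in reader:
            rid = (row.get("record_id") or "").strip()
            if not rid:
                raise InputError(f"{path}: row with empty record_id")
            if rid in seen:
                raise InputError(f"{path}: duplicate record_id {rid!r}")
            seen.add(rid)
            raw = Record(
                record_id=rid,
                dataset_id=dataset_id or (row.get("dataset_id") or "").strip() or path.stem,
                attributes={c: row.get(c) or "" for c in schema.names},
                entity_id=(row.get("entity_id") or "").strip() or None,
            )
            records.append(normalize_record(raw, schema))
    return records


def write_clusters_csv(clustering: Clustering, path: str | Path) -> None:
    """Write (cluster_id, record_id) rows sorted for byte-determinism."""
    rows = sorted(
        (cid, rid) for cid, members in clustering.items() for rid in members
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["cluster_id", "record_id"])
        writer.writerows(rows)


def read_clusters_csv(path: str | Path) -> Clustering:
    clusters: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "cluster_id" not in reader.fieldnames:
            raise InputError(f"{path}: expected columns cluster_id,record_id")
        for row in reader:
            clusters.setdefault(row["cluster_id"], set()).add(row["record_id"])
    return Clustering(clusters)


def read_truth_csv(path: str | Path) -> dict[str, str]:
    """Read record_id -> entity_id ground truth from CSV."""
    truth: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "record_id" not in reader.fieldnames:
            raise InputError(f"{path}: expected columns record_id,entity_id")
        for row in reader:
            truth[row["record_id"]] = row["entity_id"]
    return truth


_MODES = ("ed_all", "ed_name", "rded", "nded", "pded", "pd_name")
_THRESHOLD_KINDS = ("constant", "proportional")


@dataclass
class IntegrationConfig:
    """Resolved run settings: distance mode, threshold, blocking, seed.

    Defaults mirror the regime of the method's published experiments:
    truncation length 5, 3-mer blocking, constant threshold.
    """

    mode: str = "ed_all"
    threshold_kind: str = "constant"
    threshold: float = 1.0
    truncation_length: int = 5
    lmer_length: int = 3
    nickname_path: Optional[str] = None
    algorithm: str = "ids"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = str(self.mode).lower()
        self.threshold_kind = str(self.threshold_kind).lower()
        if self.mode not in _MODES:
            raise InputError(f"unknown distance mode {self.mode!r}; expected one of {_MODES}")
        if self.threshold_kind not in _THRESHOLD_KINDS:
            raise InputError(f"unknown threshold kind {self.threshold_kind!r}")
        if self.threshold < 0:
            raise InputError("threshold must be non-negative")
        if self.threshold_kind == "proportional" and not 0 <= self.threshold <= 1:
            raise InputError("proportional threshold must lie in [0, 1]")
        if self.threshold_kind == "constant" and self.threshold != int(self.threshold):
            raise InputError("constant threshold must be an integer")
        if self.truncation_length < 1:
            raise InputError("truncation_length must be >= 1")
        if self.lmer_length < 1:
            raise InputError("lmer_length must be >= 1")


def load_config(path: Optional[str | Path]) -> IntegrationConfig:
    """Load a YAML or JSON config file; absent keys fall back to defaults."""
    if path is None:
        return IntegrationConfig()
    text = Path(path).read_text(encoding="utf-8")
    try:
        import yaml

        data = yaml.safe_load(text) or {}
    except ImportError:  # pragma: no cover - yaml is a hard dependency
        data = json.loads(text or "{}")
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a mapping")
    known = {f for f in IntegrationConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
    return IntegrationConfig(**data)
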