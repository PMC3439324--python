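"""Synthetic multi-source person records with ground truth.

Generates entities (one clean original record each) and per-entity
duplicate records corrupted by the error types the distances are designed
to absorb: single-character insert/delete/substitute typos, first/last
name swaps, nickname substitution, attribute truncation, and phonetically
plausible misspellings (homophone pattern substitutions such as
``ph``→``f``).

The generator is seeded and splittable: one RNG stream per entity (spawned
from the master seed), so increasing ``n_entities`` never perturbs the
draws of earlier entities, and a fixed seed yields byte-identical CSV
output.

Defaults state a mildly corrupted world: 1-3 records per entity (uniform),
a combined per-field typo rate of 0.2 split evenly across the three edit
types, at most 2 character edits per record, name-swap probability 0.05,
nickname probability 0.1, truncation probability 0.05, phonetic
misspelling probability 0.05.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._namepools import FIRST_NAMES, NICKNAME_PAIRS, PHONETIC_RULES, SURNAMES
from .core_model import DEFAULT_SCHEMA, NicknameTable, Record

__all__ = [
    "GeneratorParams",
    "default_nickname_table",
    "generate_entities",
    "corrupt_record",
    "generate_datasets",
    "write_datasets",
    "write_truth_csv",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"
_DIGITS = "0123456789"


@dataclass
class GeneratorParams:
    """Knobs of the synthetic world; probabilities are per duplicate."""

    n_entities: int = 500
    n_datasets: int = 4
    duplicates_min: int = 1  # records per entity, uniform inclusive range
    duplicates_max: int = 3
    p_typo_insert: float = 0.2 / 3  # per field; combined typo rate ~0.2
    p_typo_delete: float = 0.2 / 3
    p_typo_substitute: float = 0.2 / 3
    p_swap_names: float = 0.05
    p_nickname: float = 0.10
    p_truncate: float = 0.05
    truncate_length: int = 5
    p_phonetic_misspell: float = 0.05
    max_edits_per_record: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities <= 0:
            raise ValueError("n_entities must be positive")
        if self.n_datasets <= 0:
            raise ValueError("n_datasets must be positive")
        if not 1 <= self.duplicates_min <= self.duplicates_max:
            raise ValueError("need 1 <= duplicates_min <= duplicates_max")
        for name in (
            "p_typo_insert", "p_typo_delete", "p_typo_substitute",
            "p_swap_names", "p_nickname", "p_truncate", "p_phonetic_misspell",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_edits_per_record < 0:
            raise ValueError("max_edits_per_record must be >= 0")


def default_nickname_table() -> NicknameTable:
    """The bundled nickname table (symmetric closure of the pair list)."""
    return NicknameTable(NICKNAME_PAIRS)


_NICK_LOOKUP: dict[str, list[str]] = {}
for _full, _short in NICKNAME_PAIRS:
    _NICK_LOOKUP.setdefault(_full, []).append(_short)
    _NICK_LOOKUP.setdefault(_short, []).append(_full)


def _entity_streams(params: GeneratorParams) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(params.seed).spawn(params.n_entities)
    return [np.random.default_rng(s) for s in seqs]


def _draw_original(entity_id: str, rng: np.random.Generator) -> Record:
    first, gender = FIRST_NAMES[rng.integers(len(FIRST_NAMES))]
    last = SURNAMES[rng.integers(len(SURNAMES))]
    year = int(rng.integers(1930, 2010))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    zipcode = f"{rng.integers(0, 100000):05d}"
    return Record(
        record_id=f"{entity_id}.0",
        dataset_id="",
        attributes={
            "first": first,
            "last": last,
            "dob": f"{year:04d}{month:02d}{day:02d}",
            "gender": gender,
            "zip": zipcode,
        },
        entity_id=entity_id,
    )


def generate_entities(params: GeneratorParams) -> list[Record]:
    """One clean original record per entity; deterministic under the seed."""
    return [
        _draw_original(f"e{i:05d}", rng)
        for i, rng in enumerate(_entity_streams(params))
    ]


def _typo(value: str, kind: str, rng: np.random.Generator) -> str:
    alphabet = _DIGITS if value.isdigit() else _LETTERS
    if kind == "insert":
        pos = int(rng.integers(0, len(value) + 1))
        return value[:pos] + alphabet[rng.integers(len(alphabet))] + value[pos:]
    if not value:
        return value
    pos = int(rng.integers(0, len(value)))
    if kind == "delete":
        return value[:pos] + value[pos + 1 :]
    ch = alphabet[rng.integers(len(alphabet))]
    return value[:pos] + ch + value[pos + 1 :]


def _phonetic_misspell(value: str, rng: np.random.Generator) -> str:
    applicable = [(src, dst) for src, dst in PHONETIC_RULES if src in value]
    if not applicable:
        return value
    src, dst = applicable[rng.integers(len(applicable))]
    return value.replace(src, dst, 1)


def corrupt_record(
    original: Record, params: GeneratorParams, rng: np.random.Generator
) -> Record:
    """One corrupted duplicate of ``original`` (same entity, new record id).

    Field-level corruptions (swap, nickname, truncation, phonetic
    misspelling) are drawn first, then character typos field by field in
    schema order, capped at ``max_edits_per_record`` character edits.
    The caller assigns the duplicate's record id suffix.
    """
    attrs = dict(original.attributes)
    if rng.random() < params.p_swap_names:
        attrs["first"], attrs["last"] = attrs["last"], attrs["first"]
    if rng.random() < params.p_nickname:
        variants = _NICK_LOOKUP.get(attrs["first"])
        if variants:
            attrs["first"] = variants[rng.integers(len(variants))]
    if rng.random() < params.p_truncate:
        attrs["first"] = attrs["first"][: params.truncate_length]
    if rng.random() < params.p_phonetic_misspell:
        which = "first" if rng.random() < 0.5 else "last"
        attrs[which] = _phonetic_misspell(attrs[which], rng)
    edits = 0
    for field_name in DEFAULT_SCHEMA.names:
        for kind, p in (
            ("insert", params.p_typo_insert),
            ("delete", params.p_typo_delete),
            ("substitute", params.p_typo_substitute),
        ):
            if edits >= params.max_edits_per_record:
                break
            if rng.random() < p:
                attrs[field_name] = _typo(attrs[field_name], kind, rng)
                edits += 1
    return Record(
        record_id=original.record_id,  # caller re-ids duplicates
        dataset_id=original.dataset_id,
        attributes=attrs,
        entity_id=original.entity_id,
    )


def generate_datasets(
    params: GeneratorParams,
) -> tuple[list[Record], dict[str, str]]:
    """All records across the synthetic datasets plus the ground truth map.

    Each entity gets a uniform ``duplicates_min..duplicates_max`` number of
    records: the clean original plus corrupted duplicates, each assigned to
    one of ``n_datasets`` sources uniformly at random.
    """
    records: list[Record] = []
    truth: dict[str, str] = {}
    for i, rng in enumerate(_entity_streams(params)):
        entity_id = f"e{i:05d}"
        original = _draw_original(entity_id, rng)
        n_copies = int(rng.integers(params.duplicates_min, params.duplicates_max + 1))
        for j in range(n_copies):
            rec = original if j == 0 else corrupt_record(original, params, rng)
            rid = f"{entity_id}.{j}"
            dsid = f"d{int(rng.integers(params.n_datasets))}"
            rec = Record(
                record_id=rid,
                dataset_id=dsid,
                attributes=rec.attributes,
                entity_id=entity_id,
            )
            records.append(rec)
            truth[rid] = entity_id
    return records, truth


def write_datasets(
    records: Iterable[Record], outdir: str | Path, n_datasets: int
) -> list[Path]:
    """Write one CSV per dataset id; deterministic row order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_ds: dict[str, list[Record]] = {f"d{i}": [] for i in range(n_datasets)}
    for rec in records:
        by_ds.setdefault(rec.dataset_id, []).append(rec)
    paths = []
    cols = ["record_id", "dataset_id", "entity_id", *DEFAULT_SCHEMA.names]
    for dsid in sorted(by_ds):
        path = outdir / f"{dsid}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(cols)
            for rec in sorted(by_ds[dsid], key=lambda r: r.record_id):
                writer.writerow(
                    [rec.record_id, rec.dataset_id, rec.entity_id or ""]
                    + [rec.get(c) for c in DEFAULT_SCHEMA.names]
                )
        paths.append(path)
    return paths


def write_truth_csv(truth: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["record_id", "entity_id"])
        for rid in sorted(truth):
            writer.writerow([rid, truth[rid]])
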