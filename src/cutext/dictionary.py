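"""Content-unit (CU) dictionaries: the scene inventory that drives all matching.

A CU dictionary enumerates the objects, actions and properties of an
elicitation picture (here the picnic scene).  Each entry groups the
morphological/synonym variants that all credit the same content unit, and
carries a fixed ambiguity label: *unambiguous* entries refer to exactly one
scene element ("dog" — there is only one dog), *ambiguous* entries could
refer to several ("running" — both the dog and the boy run).  The label is a
property of the entry, never resolved from context.

The packaged picnic fixture is a synthetic 64-entry stand-in with the same
structure as published picnic-scene CU inventories (the original corpus is
not redistributable); it ships entry #12 grouping "girl"/"daughter" so the
classic worked examples are executable.
"""

from __future__ import annotations

import csv
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CATEGORIES = ("entity", "action", "property")
AMBIGUITY = ("unambiguous", "ambiguous")
POS_CLASSES = ("noun", "verb", "adjective", "adverb", "other")

PACKAGED_PICNIC = "picnic_scene_64.tsv"


class DictionaryError(ValueError):
    """Schema or invariant violation in a CU dictionary source."""


@dataclass(frozen=True)
class CUEntry:
    """One content unit: a label plus the (lemma, pos_class) variants that credit it."""

    entry_id: int
    canonical_label: str
    category: str
    ambiguity: str
    variants: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.entry_id <= 0:
            raise DictionaryError(f"entry_id must be positive, got {self.entry_id}")
        if self.category not in CATEGORIES:
            raise DictionaryError(
                f"entry {self.entry_id}: category {self.category!r} not in {CATEGORIES}"
            )
        if self.ambiguity not in AMBIGUITY:
            raise DictionaryError(
                f"entry {self.entry_id}: ambiguity {self.ambiguity!r} not in {AMBIGUITY}"
            )
        if not self.variants:
            raise DictionaryError(f"entry {self.entry_id}: empty variant set")
        for lemma, pos in self.variants:
            if not lemma or lemma != lemma.lower():
                raise DictionaryError(
                    f"entry {self.entry_id}: lemma {lemma!r} must be non-empty lowercase"
                )
            if pos not in POS_CLASSES:
                raise DictionaryError(
                    f"entry {self.entry_id}: pos_class {pos!r} not in {POS_CLASSES}"
                )


@dataclass
class CUDictionary:
    """An ordered inventory of CU entries for one scene.

    Invariant: every (lemma, pos_class) pair maps to exactly one entry, so a
    token can credit at most one CU — this is what makes cu_count <= unit_count
    provable downstream.
    """

    scene_name: str
    entries: list[CUEntry] = field(default_factory=list)
    version: str = "1"

    def __post_init__(self) -> None:
        violations = validate_dictionary(self)
        if violations:
            raise DictionaryError("; ".join(violations))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CUDictionary):
            return NotImplemented
        return (
            self.scene_name == other.scene_name
            and self.version == other.version
            and self.entries == other.entries
        )

    def entry(self, entry_id: int) -> CUEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    def variant_map(self) -> dict[tuple[str, str], int]:
        """(lemma, pos_class) -> entry_id lookup used by the matcher."""
        out: dict[tuple[str, str], int] = {}
        for e in self.entries:
            for v in e.variants:
                out[v] = e.entry_id
        return out

    def ambiguity_of(self) -> dict[int, str]:
        return {e.entry_id: e.ambiguity for e in self.entries}


def validate_dictionary(dictionary: CUDictionary) -> list[str]:
    """Return human-readable invariant violations (empty list iff valid)."""
    violations: list[str] = []
    id_counts = Counter(e.entry_id for e in dictionary.entries)
    for eid, n in sorted(id_counts.items()):
        if n > 1:
            violations.append(f"duplicate entry_id {eid} used by {n} entries")
    seen: dict[tuple[str, str], int] = {}
    for e in dictionary.entries:
        for lemma, pos in sorted(e.variants):
            if lemma != lemma.lower():
                violations.append(
                    f"entry {e.entry_id}: lemma {lemma!r} not lowercase"
                )
            key = (lemma, pos)
            if key in seen and seen[key] != e.entry_id:
                violations.append(
                    f"variant ({lemma}, {pos}) listed under entries "
                    f"{seen[key]} and {e.entry_id}"
                )
            else:
                seen[key] = e.entry_id
    return violations


def _entry_from_fields(row: Mapping[str, object], where: str) -> CUEntry:
    try:
        eid = int(str(row["entry_id"]))
    except (KeyError, ValueError) as exc:
        raise DictionaryError(f"{where}: bad or missing entry_id ({exc})") from None
    raw_variants = row.get("variants")
    if isinstance(raw_variants, str):
        pairs = []
        for chunk in raw_variants.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "|" not in chunk:
                raise DictionaryError(f"{where}: variant {chunk!r} missing '|'")
            lemma, _, pos = chunk.partition("|")
            pairs.append((lemma.strip(), pos.strip()))
    elif isinstance(raw_variants, list):
        pairs = [(str(v["lemma"]), str(v["pos_class"])) for v in raw_variants]
    else:
        raise DictionaryError(f"{where}: missing variants field")
    for key in ("canonical_label", "category", "ambiguity"):
        if key not in row:
            raise DictionaryError(f"{where}: missing field {key!r}")
    try:
        return CUEntry(
            entry_id=eid,
            canonical_label=str(row["canonical_label"]),
            category=str(row["category"]),
            ambiguity=str(row["ambiguity"]),
            variants=frozenset(pairs),
        )
    except DictionaryError as exc:
        raise DictionaryError(f"{where}: {exc}") from None


def load_dictionary(path: str | Path, format: str | None = None) -> CUDictionary:
    """Load a CU dictionary from TSV or JSON (see the file-format docs).

    TSV columns: entry_id, canonical_label, category, ambiguity, variants
    (semicolon-separated ``lemma|pos`` pairs); header row required.  JSON is
    either a bare array of entry objects or an object with ``scene_name``,
    ``version`` and ``entries``.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt not in ("tsv", "json"):
        raise DictionaryError(f"unknown dictionary format {fmt!r}")
    entries: list[CUEntry] = []
    scene_name = path.stem
    version = "1"
    if fmt == "tsv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"entry_id", "canonical_label", "category", "ambiguity", "variants"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise DictionaryError(
                    f"{path}: header must contain {sorted(required)}"
                )
            for lineno, row in enumerate(reader, start=2):
                entries.append(_entry_from_fields(row, f"{path}:{lineno}"))
    else:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            scene_name = payload.get("scene_name", scene_name)
            version = str(payload.get("version", version))
            raw_entries = payload["entries"]
        else:
            raw_entries = payload
        for i, row in enumerate(raw_entries):
            entries.append(_entry_from_fields(row, f"{path}: entry[{i}]"))
    return CUDictionary(scene_name=scene_name, entries=entries, version=version)


def save_dictionary(dictionary: CUDictionary, path: str | Path, format: str | None = None) -> None:
    """Write a dictionary back out; ``load(save(d)) == d`` for both formats."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["entry_id", "canonical_label", "category", "ambiguity", "variants"])
            for e in dictionary.entries:
                variants = ";".join(f"{l}|{p}" for l, p in sorted(e.variants))
                writer.writerow([e.entry_id, e.canonical_label, e.category, e.ambiguity, variants])
    elif fmt == "json":
        payload = {
            "scene_name": dictionary.scene_name,
            "version": dictionary.version,
            "entries": [
                {
                    "entry_id": e.entry_id,
                    "canonical_label": e.canonical_label,
                    "category": e.category,
                    "ambiguity": e.ambiguity,
                    "variants": [
                        {"lemma": l, "pos_class": p} for l, p in sorted(e.variants)
                    ],
                }
                for e in dictionary.entries
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)
            fh.write("\n")
    else:
        raise DictionaryError(f"unknown dictionary format {fmt!r}")


def load_packaged_dictionary() -> CUDictionary:
    """The packaged 64-entry picnic-scene fixture (synthetic stand-in inventory)."""
    with resources.as_file(
        resources.files("cutext.data").joinpath(PACKAGED_PICNIC)
    ) as p:
        d = load_dictionary(p, format="tsv")
    d.scene_name = "picnic_scene"
    return d


def compile_dictionary(
    control_mentions: Sequence[Iterable[tuple[str, str, str]]],
    min_controls: int = 3,
    *,
    candidate_meta: Mapping[str, tuple[str, str]] | None = None,
    scene_name: str = "compiled",
) -> CUDictionary:
    """Compile a CU dictionary from healthy-control mentions.

    A candidate content unit is admitted when at least ``min_controls``
    distinct controls mentioned it — the standard criterion for building a
    picture-specific CU corpus from control descriptions.

    Parameters
    ----------
    control_mentions:
        One collection per control of ``(lemma, pos_class, candidate_label)``
        triples; morphological variants are merged by shared candidate_label.
    min_controls:
        Minimum number of distinct controls per admitted candidate (>= 1).
    candidate_meta:
        Optional ``candidate_label -> (category, ambiguity)``; defaults to
        ("entity", "unambiguous").
    """
    if min_controls < 1:
        raise ValueError(f"min_controls must be >= 1, got {min_controls}")
    if len(control_mentions) < min_controls:
        raise ValueError(
            f"need at least {min_controls} controls, got {len(control_mentions)}"
        )
    support: dict[str, set[int]] = defaultdict(set)
    variants: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for idx, mentions in enumerate(control_mentions):
        for lemma, pos, label in mentions:
            support[label].add(idx)
            variants[label].add((lemma.lower(), pos))
    admitted = sorted(
        label for label, who in support.items() if len(who) >= min_controls
    )
    meta = candidate_meta or {}
    entries = [
        CUEntry(
            entry_id=i,
            canonical_label=label,
            category=meta.get(label, ("entity", "unambiguous"))[0],
            ambiguity=meta.get(label, ("entity", "unambiguous"))[1],
            variants=frozenset(variants[label]),
        )
        for i, label in enumerate(admitted, start=1)
    ]
    return CUDictionary(scene_name=scene_name, entries=entries, version="compiled")
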