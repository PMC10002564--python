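"""Dataset model and tab-separated I/O for DDI event prediction.

Three plain-text inputs describe a study: a DDI event table
``(drug_a, drug_b, event)``, a drug table ``(drug_id, smiles)`` and a
knowledge-graph triplet table ``(head, relation, tail)`` in which drug ids
appear as entities.  All files are UTF-8, tab-separated, headerless by
default (the DRKG triplet-file convention); blank lines are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Drug",
    "DDIRecord",
    "EventVocabulary",
    "KGTriplet",
    "DatasetBundle",
    "ParseError",
    "ValidationError",
    "read_drug_table",
    "read_ddi_table",
    "read_kg_triplets",
    "assemble_bundle",
    "write_drug_table",
    "write_ddi_table",
    "write_kg_triplets",
    "load_bundle",
    "save_bundle",
]


class ParseError(ValueError):
    """A malformed input line (message carries the 1-based line number)."""


class ValidationError(ValueError):
    """Parsed content violates a dataset invariant."""


@dataclass(frozen=True)
class Drug:
    drug_id: str
    smiles: str

    def __post_init__(self):
        if not self.smiles:
            raise ValidationError(f"drug {self.drug_id!r} has an empty SMILES")


@dataclass(frozen=True)
class DDIRecord:
    drug_i: str
    drug_j: str
    event: int  # index into the event vocabulary


@dataclass
class EventVocabulary:
    """Bijection between event names and indices, stable across save/load."""

    labels: list[str]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("event labels must be unique")
        self._index = {name: i for i, name in enumerate(self.labels)}

    @property
    def n_events(self) -> int:
        return len(self.labels)

    def index(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class KGTriplet:
    head: str
    relation: str
    tail: str

    def __post_init__(self):
        if not (self.head and self.relation and self.tail):
            raise ValidationError("KG triplet fields must be non-empty")


@dataclass
class DatasetBundle:
    """Drugs, their DDI records, the KG, and the event vocabulary."""

    drugs: list[Drug]
    ddis: list[DDIRecord]
    triplets: list[KGTriplet]
    events: EventVocabulary
    warnings: list[str] = field(default_factory=list)

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    def drug_index(self) -> dict[str, int]:
        return {d.drug_id: i for i, d in enumerate(self.drugs)}

    def kg_entities(self) -> set[str]:
        ents: set[str] = set()
        for t in self.triplets:
            ents.add(t.head)
            ents.add(t.tail)
        return ents


def _read_rows(path, n_cols: int, header: bool):
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue  # blank lines carry no record
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append((lineno, parts))
    return rows


def read_drug_table(path, header: bool = False) -> list[Drug]:
    """Read the ``(drug_id, smiles)`` table; drug ids must be unique."""
    drugs = []
    seen: set[str] = set()
    for lineno, (drug_id, smiles) in ((ln, p) for ln, p in _read_rows(path, 2, header)):
        if drug_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate drug id {drug_id!r}")
        seen.add(drug_id)
        drugs.append(Drug(drug_id, smiles))
    return drugs


def read_ddi_table(path, events: EventVocabulary | None = None,
                   header: bool = False) -> tuple[list[DDIRecord], EventVocabulary]:
    """Read the DDI event table.

    When ``events`` is not supplied the vocabulary is built from unique
    labels in first-appearance order, which makes index assignment a
    deterministic function of file content.  Self-pairs and duplicate
    unordered pairs are rejected.
    """
    labels: list[str] = list(events.labels) if events is not None else []
    index = {name: i for i, name in enumerate(labels)}
    records: list[DDIRecord] = []
    seen_pairs: set[frozenset] = set()
    for lineno, (a, b, label) in ((ln, p) for ln, p in _read_rows(path, 3, header)):
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-pair ({a!r}, {b!r})")
        key = frozenset((a, b))
        if key in seen_pairs:
            raise ValidationError(
                f"{path}:{lineno}: duplicate unordered pair ({a!r}, {b!r})"
            )
        seen_pairs.add(key)
        if label not in index:
            if events is not None:
                raise ValidationError(
                    f"{path}:{lineno}: event {label!r} not in supplied vocabulary"
                )
            index[label] = len(labels)
            labels.append(label)
        records.append(DDIRecord(a, b, index[label]))
    return records, EventVocabulary(labels)


def read_kg_triplets(path, header: bool = False) -> list[KGTriplet]:
    """Read ``(head, relation, tail)`` triplets; duplicates retained
    (the translational trainer treats the KG as a multiset)."""
    return [KGTriplet(h, r, t) for _, (h, r, t) in _read_rows(path, 3, header)]


def assemble_bundle(drugs: list[Drug], ddis: list[DDIRecord],
                    triplets: list[KGTriplet],
                    events: EventVocabulary) -> DatasetBundle:
    """Cross-reference the parsed components into a bundle.

    A DDI record naming an unknown drug is a hard error.  Drugs absent from
    the KG entity set are usable (they receive a zero network embedding
    downstream) but are recorded in ``bundle.warnings``.
    """
    ids = {d.drug_id for d in drugs}
    if len(ids) != len(drugs):
        raise ValidationError("duplicate drug ids in drug list")
    for rec in ddis:
        for did in (rec.drug_i, rec.drug_j):
            if did not in ids:
                raise ValidationError(f"DDI record references unknown drug {did!r}")
        if not (0 <= rec.event < events.n_events):
            raise ValidationError(
                f"DDI event index {rec.event} outside vocabulary of size {events.n_events}"
            )
    entities = set()
    for t in triplets:
        entities.add(t.head)
        entities.add(t.tail)
    warn_list = [
        f"drug {d.drug_id!r} does not appear as a KG entity; "
        "its network embedding will be the zero vector"
        for d in drugs
        if d.drug_id not in entities
    ]
    for w in warn_list:
        warnings.warn(w, stacklevel=2)
    return DatasetBundle(list(drugs), list(ddis), list(triplets), events, warn_list)


# -- writers (round-trip partners of the readers) ------------------------

def write_drug_table(drugs: list[Drug], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in drugs:
            fh.write(f"{d.drug_id}\t{d.smiles}\n")


def write_ddi_table(ddis: list[DDIRecord], events: EventVocabulary, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in ddis:
            fh.write(f"{r.drug_i}\t{r.drug_j}\t{events.labels[r.event]}\n")


def write_kg_triplets(triplets: list[KGTriplet], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in triplets:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def save_bundle(bundle: DatasetBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_drug_table(bundle.drugs, out / "drugs.tsv")
    write_ddi_table(bundle.ddis, bundle.events, out / "ddis.tsv")
    write_kg_triplets(bundle.triplets, out / "kg.tsv")
    # vocabulary written explicitly so indices survive even when some event
    # never occurs in the record list
    with (out / "events.tsv").open("w", encoding="utf-8") as fh:
        for name in bundle.events.labels:
            fh.write(name + "\n")


def load_bundle(in_dir) -> DatasetBundle:
    src = Path(in_dir)
    drugs = read_drug_table(src / "drugs.tsv")
    vocab_path = src / "events.tsv"
    events = None
    if vocab_path.exists():
        labels = [
            ln.rstrip("\n")
            for ln in vocab_path.read_text(encoding="utf-8").splitlines()
            if ln.strip()
        ]
        events = EventVocabulary(labels)
    ddis, events = read_ddi_table(src / "ddis.tsv", events=events)
    triplets = read_kg_triplets(src / "kg.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_bundle(drugs, ddis, triplets, events)
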