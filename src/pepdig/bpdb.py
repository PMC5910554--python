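"""Non-redundant bioactive-peptide database built from heterogeneous sources.

Public bioactive-peptide collections come as tab-separated tables or as
FASTA with annotation in the header.  Ingestion normalises each source to
raw (sequence, activity, record_id) triples; merging unions activities and
source provenance per unique sequence, so a peptide reported by several
databases (possibly under different activities) becomes one entry that can
be traced back to all of them.

The persistent format is a headered TSV (one entry per line; activities
";"-joined; sources "db:record"-pairs ";"-joined) — diff-able and trivially
parseable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .digestion import classify_length, LENGTH_CLASSES
from .rules import VALID_RESIDUES

__all__ = [
    "SourceDescriptor",
    "BioactiveEntry",
    "BioactiveDB",
    "IngestResult",
    "ingest_source",
    "merge_sources",
    "partition_by_length",
    "db_stats",
    "save_db",
    "load_db",
]

_FORMAT_SENTINEL = "## pepdig-bpdb v1"


@dataclass(frozen=True)
class SourceDescriptor:
    """How to read one source table.

    For ``format="tsv"``, *sequence_field*, *activity_field* and *id_field*
    name columns.  For ``format="fasta"`` the record id is the FASTA id and
    the activity is taken from the description: the whole description by
    default, or the value of a ``key=value`` token when *activity_field*
    is set to that key.
    """

    db_name: str
    format: str  # "tsv" | "fasta"
    sequence_field: str = "sequence"
    activity_field: str = "activity"
    id_field: str = "record_id"
    accessed_date: str = ""

    def __post_init__(self):
        if not self.db_name:
            raise ValueError("db_name must be non-empty")
        if self.format not in ("tsv", "fasta"):
            raise ValueError(f"unsupported source format {self.format!r}")
        if not self.sequence_field:
            raise ValueError("descriptor must name a sequence field")


@dataclass
class IngestResult:
    db_name: str
    records: list  # (sequence, activity, record_id)
    skipped: list  # (location, reason)

    @property
    def n_skipped(self):
        return len(self.skipped)


@dataclass
class BioactiveEntry:
    sequence: str
    activities: set
    sources: set  # (db_name, record_id)

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValueError(f"entry sequence too short: {self.sequence!r}")
        if not self.activities or not self.sources:
            raise ValueError(f"entry {self.sequence}: activities and sources must be non-empty")

    @property
    def length_class(self):
        return classify_length(self.sequence)


@dataclass
class BioactiveDB:
    """Entries keyed by sequence, plus build metadata."""

    entries: dict = field(default_factory=dict)  # sequence -> BioactiveEntry
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def __contains__(self, sequence):
        return sequence in self.entries

    def sequences(self):
        return sorted(self.entries)

    def source_names(self):
        names = set()
        for entry in self.entries.values():
            names.update(db for db, _ in entry.sources)
        return sorted(names)


def _valid_peptide(seq: str) -> bool:
    return len(seq) >= 2 and bool(seq) and set(seq) <= VALID_RESIDUES


def ingest_source(path, descriptor: SourceDescriptor) -> IngestResult:
    """Read one source into raw records; invalid sequences go to a skip report."""
    records, skipped = [], []

    def push(raw_seq, activity, record_id, where):
        seq = (raw_seq or "").strip().upper()
        activity = (activity or "").strip()
        if not seq or not _valid_peptide(seq):
            skipped.append((where, f"invalid sequence {raw_seq!r}"))
            return
        records.append((seq, activity or "unannotated", str(record_id)))

    if descriptor.format == "tsv":
        try:
            table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except Exception as exc:
            raise ValueError(f"cannot parse TSV {path}: {exc}") from exc
        for col in (descriptor.sequence_field, descriptor.activity_field, descriptor.id_field):
            if col not in table.columns:
                raise ValueError(
                    f"{path}: column {col!r} not found (have {list(table.columns)})"
                )
        for row_idx, row in table.iterrows():
            push(
                row[descriptor.sequence_field],
                row[descriptor.activity_field],
                row[descriptor.id_field],
                f"{path}:line {row_idx + 2}",
            )
    else:  # fasta
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description[len(rec.id) :].strip() if rec.description else ""
            activity = desc
            if descriptor.activity_field and "=" in desc:
                for token in desc.split():
                    if token.startswith(descriptor.activity_field + "="):
                        activity = token.split("=", 1)[1]
                        break
            push(str(rec.seq), activity, rec.id, f"{path}:{rec.id}")
    return IngestResult(descriptor.db_name, records, skipped)


def merge_sources(ingests: Sequence[IngestResult]) -> BioactiveDB:
    """Union raw sources into one entry per unique sequence.

    Activities and provenance are set unions, so the result is independent
    of source order.
    """
    if not ingests:
        raise ValueError("no sources to merge")
    entries: dict = {}
    for ingest in ingests:
        for seq, activity, record_id in ingest.records:
            entry = entries.get(seq)
            if entry is None:
                entries[seq] = BioactiveEntry(seq, {activity}, {(ingest.db_name, record_id)})
            else:
                entry.activities.add(activity)
                entry.sources.add((ingest.db_name, record_id))
    if not entries:
        raise ValueError("merged database is empty — check source files and descriptors")
    meta = {
        "sources": ";".join(sorted({i.db_name for i in ingests})),
        "n_entries": str(len(entries)),
    }
    return BioactiveDB(entries=entries, metadata=meta)


def partition_by_length(db: BioactiveDB) -> dict:
    """Disjoint cover of entries by length group (very_short / short / long)."""
    parts = {group: [] for group in LENGTH_CLASSES}
    for seq in sorted(db.entries):
        parts[db.entries[seq].length_class].append(db.entries[seq])
    return parts


def db_stats(db: BioactiveDB) -> dict:
    """Count entries per source database, per activity, and per length group.

    An entry found in several sources counts toward each of them; the
    ``total`` is the number of unique entries.
    """
    per_source: dict = {}
    per_activity: dict = {}
    per_length = {group: 0 for group in LENGTH_CLASSES}
    for entry in db.entries.values():
        for db_name in {name for name, _ in entry.sources}:
            per_source[db_name] = per_source.get(db_name, 0) + 1
        for act in entry.activities:
            per_activity[act] = per_activity.get(act, 0) + 1
        per_length[entry.length_class] += 1
    return {
        "total": len(db.entries),
        "per_source": pd.Series(per_source, dtype=int).sort_index(),
        "per_activity": pd.Series(per_activity, dtype=int).sort_index(),
        "per_length": pd.Series(per_length, dtype=int),
    }


def save_db(db: BioactiveDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_FORMAT_SENTINEL + "\n")
        for key in sorted(db.metadata):
            fh.write(f"## {key}={db.metadata[key]}\n")
        fh.write("sequence\tactivities\tsources\n")
        for seq in sorted(db.entries):
            entry = db.entries[seq]
            acts = ";".join(sorted(entry.activities))
            srcs = ";".join(f"{d}:{r}" for d, r in sorted(entry.sources))
            fh.write(f"{seq}\t{acts}\t{srcs}\n")


def load_db(path) -> BioactiveDB:
    """Load a database written by :func:`save_db` (round-trip identity)."""
    entries: dict = {}
    metadata: dict = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _FORMAT_SENTINEL:
            raise ValueError(
                f"{path}: not a pepdig bioactive DB (expected leading {_FORMAT_SENTINEL!r})"
            )
        header_seen = False
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("## "):
                key, _, value = line[3:].partition("=")
                metadata[key] = value
                continue
            if not header_seen:
                if line != "sequence\tactivities\tsources":
                    raise ValueError(f"{path}:{lineno}: bad column header {line!r}")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            seq, acts, srcs = fields
            sources = set()
            for pair in srcs.split(";"):
                db_name, _, record_id = pair.partition(":")
                if not db_name or not record_id:
                    raise ValueError(f"{path}:{lineno}: bad source token {pair!r}")
                sources.add((db_name, record_id))
            entries[seq] = BioactiveEntry(seq, set(acts.split(";")), sources)
    if not header_seen:
        raise ValueError(f"{path}: truncated file (no column header)")
    if not entries:
        raise ValueError(f"{path}: database holds no entries")
    return BioactiveDB(entries=entries, metadata=metadata)
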