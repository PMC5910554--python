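"""Bioactivity identification: 100%-identity matching with full coverage.

A digested peptide is identified as bioactive when it aligns to a database
entry at 100% identity with full coverage of the query (the peptide) or the
subject (the database entry).  At full identity this reduces to substring
containment, so matching needs no aligner:

* ``equal``                — peptide and entry are the same sequence;
* ``contains_subject``    — a database entry lies inside the peptide;
* ``contained_in_subject`` — the peptide lies inside a database entry.

Exact lookup is a hash probe; containment in either direction is a single
Aho-Corasick scan (db entries over each peptide, and peptides over each db
entry).  Matched peptides are back-tracked to their origin proteins for the
"list all" table, and per-protein tallies form the "summary" table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._ahocorasick import AhoCorasick
from .bpdb import BioactiveDB, BioactiveEntry
from .digestion import DigestResult, NonRedundantPeptide, ProteinRecord

__all__ = [
    "MATCH_MODES",
    "MatchHit",
    "MatchRecord",
    "MatchIndex",
    "build_match_index",
    "match_peptides",
    "backtrack",
    "summarize",
    "export_list_all",
    "export_summary",
    "export_counts",
    "counts_grid",
]

MATCH_MODES = ("exact", "query_covered", "subject_covered", "either")


@dataclass(frozen=True)
class MatchHit:
    entry: BioactiveEntry
    relation: str  # equal | contains_subject | contained_in_subject
    offset: int  # 0-based offset of the covered region within the longer sequence

    def __post_init__(self):
        if self.relation not in ("equal", "contains_subject", "contained_in_subject"):
            raise ValueError(f"bad relation {self.relation!r}")
        if self.offset < 0:
            raise ValueError("negative offset")


@dataclass
class MatchRecord:
    peptide: NonRedundantPeptide
    hits: list  # [MatchHit], deterministic order

    def activities(self):
        acts = set()
        for hit in self.hits:
            acts.update(hit.entry.activities)
        return sorted(acts)

    def source_dbs(self):
        names = set()
        for hit in self.hits:
            names.update(db for db, _ in hit.entry.sources)
        return sorted(names)


class MatchIndex:
    """Exact-lookup dict + multi-pattern automaton over the db sequences."""

    def __init__(self, db: BioactiveDB):
        self.db = db
        self.sequences = sorted(db.entries)
        self._automaton = AhoCorasick(self.sequences)

    def exact(self, sequence: str):
        return self.db.entries.get(sequence)

    def scan(self, text: str):
        """All (entry, start) with entry.sequence contained in ``text`` (0-based start)."""
        seen = set()
        for idx, start in self._automaton.scan(text):
            key = (idx, start)
            if key not in seen:  # first occurrence per (pattern, position) pair
                seen.add(key)
                yield self.db.entries[self.sequences[idx]], start


def build_match_index(db: BioactiveDB) -> MatchIndex:
    return MatchIndex(db)


def match_peptides(
    peptides: Iterable[NonRedundantPeptide],
    index: MatchIndex,
    mode: str = "either",
) -> list:
    """Return a MatchRecord for every peptide with >= 1 hit under ``mode``."""
    if mode not in MATCH_MODES:
        raise ValueError(f"mode must be one of {MATCH_MODES}, got {mode!r}")
    peptides = list(peptides)

    want_equal = True  # equality satisfies every mode's coverage criterion
    want_contains = mode in ("subject_covered", "either")
    want_contained = mode in ("query_covered", "either")

    hits_by_key: dict = {}

    def add(pep, entry, relation, offset):
        # first-seen offset wins when a pattern occurs several times
        hits_by_key.setdefault(pep.key, {}).setdefault(
            (entry.sequence, relation), MatchHit(entry, relation, offset)
        )

    for pep in peptides:
        if want_equal:
            entry = index.exact(pep.sequence)
            if entry is not None:
                add(pep, entry, "equal", 0)
        if want_contains:
            for entry, start in index.scan(pep.sequence):
                if len(entry.sequence) < len(pep.sequence):
                    add(pep, entry, "contains_subject", start)

    if want_contained:
        # Scan db entries with an automaton over the (deduplicated) peptides.
        unique_seqs = sorted({p.sequence for p in peptides})
        if unique_seqs:
            automaton = AhoCorasick(unique_seqs)
            first_offset: dict = {}
            for db_seq in index.sequences:
                seen = set()
                for idx, start in automaton.scan(db_seq):
                    if idx in seen:
                        continue
                    seen.add(idx)
                    pep_seq = unique_seqs[idx]
                    if len(pep_seq) < len(db_seq):
                        first_offset.setdefault(pep_seq, []).append((db_seq, start))
            for pep in peptides:
                for db_seq, start in first_offset.get(pep.sequence, []):
                    add(pep, index.db.entries[db_seq], "contained_in_subject", start)

    records = []
    for pep in peptides:
        hits = hits_by_key.get(pep.key)
        if hits:
            ordered = [hits[k] for k in sorted(hits)]
            records.append(MatchRecord(pep, ordered))
    return records


def backtrack(match_records: Sequence[MatchRecord]) -> pd.DataFrame:
    """The "list all" table: one row per matched (peptide, enzyme, level).

    Origin proteins are comma-joined in first-occurrence order; activities
    and source databases are ";"-joined lexicographically.
    """
    rows = []
    for rec in sorted(match_records, key=lambda r: (r.peptide.enzyme_id, r.peptide.level, r.peptide.sequence)):
        pep = rec.peptide
        rows.append(
            {
                "peptide": pep.sequence,
                "enzyme": pep.enzyme_id,
                "miscleavage": pep.level,
                "length_class": pep.length_class,
                "origin_proteins": ",".join(pep.origin_proteins()),
                "n_occurrences": len(pep.occurrences),
                "activities": ";".join(rec.activities()),
                "source_dbs": ";".join(rec.source_dbs()),
                "relations": ";".join(sorted({h.relation for h in rec.hits})),
            }
        )
    columns = [
        "peptide", "enzyme", "miscleavage", "length_class", "origin_proteins",
        "n_occurrences", "activities", "source_dbs", "relations",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize(
    match_records: Sequence[MatchRecord],
    proteins: Sequence[ProteinRecord],
    all_peptides: Iterable[NonRedundantPeptide] | None = None,
) -> pd.DataFrame:
    """The "summary" table: one row per input protein (zero-hit rows included).

    The bioactive count is the number of distinct matched (sequence, enzyme,
    level) peptides with at least one occurrence in the protein; a peptide
    found in several proteins counts once per origin.
    """
    per_protein_bio: dict = {p.protein_id: set() for p in proteins}
    per_protein_acts: dict = {p.protein_id: set() for p in proteins}
    for rec in match_records:
        for pid in rec.peptide.origin_proteins():
            if pid not in per_protein_bio:
                raise ValueError(f"match references unknown protein {pid!r}")
            per_protein_bio[pid].add(rec.peptide.key)
            per_protein_acts[pid].update(rec.activities())
    per_protein_pep: dict = {p.protein_id: set() for p in proteins}
    if all_peptides is not None:
        for pep in all_peptides:
            for pid in pep.origin_proteins():
                if pid in per_protein_pep:
                    per_protein_pep[pid].add(pep.key)
    rows = []
    for protein in proteins:
        pid = protein.protein_id
        rows.append(
            {
                "protein_id": pid,
                "protein_length": len(protein),
                "n_peptides": len(per_protein_pep[pid]) if all_peptides is not None else "",
                "n_bioactive_peptides": len(per_protein_bio[pid]),
                "activities": ";".join(sorted(per_protein_acts[pid])),
            }
        )
    columns = ["protein_id", "protein_length", "n_peptides", "n_bioactive_peptides", "activities"]
    return pd.DataFrame(rows, columns=columns)


def counts_grid(result: DigestResult, match_records: Sequence[MatchRecord]) -> pd.DataFrame:
    """Per enzyme x miscleavage level: peptide count, bioactive count, percentage.

    The percentage is bioactive/peptides on the non-redundant peptide counts,
    printed with two decimals.
    """
    matched_keys = {rec.peptide.key for rec in match_records}
    rows = []
    for enzyme_id, level in result.cells():
        n_pep = result.peptide_count(enzyme_id, level)
        n_bio = sum(
            1 for p in result.peptides[(enzyme_id, level)] if p.key in matched_keys
        )
        pct = (100.0 * n_bio / n_pep) if n_pep else 0.0
        rows.append(
            {
                "enzyme": enzyme_id,
                "miscleavage": level,
                "n_peptides": n_pep,
                "n_bioactive": n_bio,
                "bioactive_pct": f"{pct:.2f}",
            }
        )
    return pd.DataFrame(
        rows, columns=["enzyme", "miscleavage", "n_peptides", "n_bioactive", "bioactive_pct"]
    )


def _export_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def export_list_all(rows: pd.DataFrame, path) -> None:
    _export_csv(rows, path)


def export_summary(rows: pd.DataFrame, path) -> None:
    _export_csv(rows, path)


def export_counts(
    result: DigestResult, match_records: Sequence[MatchRecord], path
) -> pd.DataFrame:
    grid = counts_grid(result, match_records)
    _export_csv(grid, path)
    return grid
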