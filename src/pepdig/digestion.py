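"""In silico digestion: coordinate-anchored fragments at exact miscleavage levels.

Digesting a protein with a protease at every predicted site yields the
level-0 fragments, which partition the sequence.  A peptide with exactly m
missed cleavages (an uncut site at one or more internal boundaries) is the
concatenation of m+1 consecutive level-0 fragments, so the level-m products
are sliding windows of size m+1 over the base fragments; a protein with n
base fragments has max(0, n - m) of them.  Levels are reported separately
(exact counts, never pooled or cumulative).

Peptides are deduplicated across the whole input collection by the key
(sequence, enzyme, level), each unique peptide carrying the full set of its
(protein, start, end) occurrences for later back-tracking.  Coordinates are
1-based inclusive throughout, matching the GFF3 output convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .rules import (
    CleavageRule,
    RuleSet,
    VALID_RESIDUES,
    find_cleavage_sites,
    load_builtin_rules,
)

__all__ = [
    "ProteinRecord",
    "PeptideFragment",
    "NonRedundantPeptide",
    "DigestResult",
    "read_fasta",
    "base_fragments",
    "window_fragments",
    "digest_protein",
    "digest_collection",
    "classify_length",
    "LENGTH_CLASSES",
]

#: Peptide length classes: di-/tri-peptides, 4-29 residues, and longer.
LENGTH_CLASSES = ("very_short", "short", "long")


def classify_length(sequence: str):
    """Assign a peptide to its length group: 2-3 / 4-29 / >= 30 residues."""
    n = len(sequence)
    if n < 2:
        raise ValueError(f"peptide {sequence!r} below classification domain (length >= 2)")
    if n <= 3:
        return "very_short"
    if n <= 29:
        return "short"
    return "long"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.protein_id or any(c.isspace() for c in self.protein_id):
            raise ValueError(f"invalid protein id {self.protein_id!r}")
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: invalid residues {sorted(bad)} "
                "(20 standard codes plus B/J/Z/X/U/O allowed)"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideFragment:
    """A protein-anchored digestion product at an exact miscleavage level."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    enzyme_id: str
    level: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span {self.start}..{self.end}"
            )
        if self.level < 0:
            raise ValueError("negative miscleavage level")


@dataclass
class NonRedundantPeptide:
    """Unique (sequence, enzyme, level) with all its occurrences.

    ``occurrences`` is kept in first-encounter order so downstream reports
    can list origin proteins deterministically.
    """

    sequence: str
    enzyme_id: str
    level: int
    occurrences: list = field(default_factory=list)  # (protein_id, start, end)

    @property
    def key(self):
        return (self.sequence, self.enzyme_id, self.level)

    @property
    def length_class(self):
        return classify_length(self.sequence)

    def origin_proteins(self):
        """Distinct origin protein ids, first-occurrence order."""
        seen, out = set(), []
        for pid, _, _ in self.occurrences:
            if pid not in seen:
                seen.add(pid)
                out.append(pid)
        return out


@dataclass
class DigestResult:
    """Per-(enzyme, level) fragments and non-redundant peptides."""

    enzyme_ids: list
    max_level: int
    min_len: int
    fragments: dict = field(default_factory=dict)  # (enzyme, level) -> [PeptideFragment]
    peptides: dict = field(default_factory=dict)  # (enzyme, level) -> [NonRedundantPeptide]

    def cells(self):
        for enzyme_id in self.enzyme_ids:
            for level in range(self.max_level + 1):
                yield enzyme_id, level

    def fragment_count(self, enzyme_id, level):
        return len(self.fragments[(enzyme_id, level)])

    def peptide_count(self, enzyme_id, level):
        return len(self.peptides[(enzyme_id, level)])

    def all_peptides(self):
        for cell in self.cells():
            yield from self.peptides[cell]


def read_fasta(path) -> list:
    """Read a multi-record FASTA into validated ProteinRecords.

    Duplicate identifiers are rejected (the error names the offending id).
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def base_fragments(protein: ProteinRecord, rule: CleavageRule) -> list:
    """Level-0 fragments: split at every cleavage site; they partition the protein."""
    seq = protein.sequence
    sites = find_cleavage_sites(seq, rule)
    bounds = [0] + sites + [len(seq)]
    return [
        PeptideFragment(
            protein_id=protein.protein_id,
            start=lo + 1,
            end=hi,
            sequence=seq[lo:hi],
            enzyme_id=rule.enzyme_id,
            level=0,
        )
        for lo, hi in zip(bounds, bounds[1:])
    ]


def window_fragments(base: Sequence[PeptideFragment], m: int) -> list:
    """Exact level-m products: windows of m+1 consecutive base fragments."""
    if m < 0:
        raise ValueError("miscleavage level must be >= 0")
    if m == 0:
        return list(base)
    out = []
    for i in range(len(base) - m):
        first, last = base[i], base[i + m]
        out.append(
            PeptideFragment(
                protein_id=first.protein_id,
                start=first.start,
                end=last.end,
                sequence="".join(f.sequence for f in base[i : i + m + 1]),
                enzyme_id=first.enzyme_id,
                level=m,
            )
        )
    return out


def digest_protein(
    protein: ProteinRecord,
    rule: CleavageRule,
    max_level: int = 0,
    _strict_bound: bool = True,
) -> dict:
    """Digest one protein, returning {level: [PeptideFragment]} for 0..max_level."""
    if _strict_bound and not 0 <= max_level <= 3:
        raise ValueError(f"max_level must be in 0..3, got {max_level}")
    base = base_fragments(protein, rule)
    return {m: window_fragments(base, m) for m in range(max_level + 1)}


def digest_collection(
    proteins: Sequence[ProteinRecord],
    enzyme_ids: Iterable[str],
    max_level: int = 0,
    min_len: int = 2,
    ruleset: RuleSet | None = None,
) -> DigestResult:
    """Digest a protein collection with several enzymes and deduplicate.

    Fragments shorter than ``min_len`` are excluded; the remainder are
    grouped into non-redundant peptides keyed by (sequence, enzyme, level)
    with every occurrence retained.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein collection")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dup}")
    ruleset = ruleset if ruleset is not None else load_builtin_rules()
    enzyme_ids = list(enzyme_ids)
    if not enzyme_ids:
        raise ValueError("no enzymes selected")
    rules = [ruleset.get(e) for e in enzyme_ids]

    result = DigestResult(enzyme_ids=enzyme_ids, max_level=max_level, min_len=min_len)
    for cell in result.cells():
        result.fragments[cell] = []
        result.peptides[cell] = []
    index: dict = {}
    for rule in rules:
        for protein in proteins:
            per_level = digest_protein(protein, rule, max_level)
            for level, frags in per_level.items():
                cell = (rule.enzyme_id, level)
                for frag in frags:
                    if len(frag.sequence) < min_len:
                        continue
                    result.fragments[cell].append(frag)
                    key = (frag.sequence, rule.enzyme_id, level)
                    pep = index.get(key)
                    if pep is None:
                        pep = NonRedundantPeptide(frag.sequence, rule.enzyme_id, level)
                        index[key] = pep
                        result.peptides[cell].append(pep)
                    pep.occurrences.append((frag.protein_id, frag.start, frag.end))
    return result
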