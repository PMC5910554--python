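"""Synthetic proteomes and fixture bioactive databases for pipeline validation.

``random_proteome`` draws proteins from a residue-composition model; the
default composition is uniform with lysine and arginine jointly boosted to
~11% so tryptic fragments have realistic lengths (a flat 5%-per-residue
alphabet yields implausibly long fragments).

``plant_peptides`` inserts chosen peptides into a proteome with flanking
context engineered so the selected enzyme releases them, then *verifies*
each insertion by re-scanning the modified protein with the cleavage-rule
engine: the peptide must appear with cleavage boundaries (or termini) at
both ends and no more than ``max_level`` uncut sites inside.  Failed draws
are retried; success is therefore guaranteed by construction, which turns
full-pipeline recovery into a hard gate rather than a statistical check.

``make_fixture_db`` builds a deterministic multi-source bioactive database
spanning all three length groups, with controlled overlap between
pseudo-sources to exercise the merge-union semantics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bpdb import BioactiveDB, IngestResult, merge_sources, save_db
from .digestion import ProteinRecord
from .rules import (
    CleavageRule,
    STANDARD_RESIDUES,
    find_cleavage_sites,
    is_cleavage_boundary,
)

__all__ = [
    "DEFAULT_COMPOSITION",
    "PlantManifest",
    "PlantingError",
    "random_proteome",
    "plant_peptides",
    "releasable",
    "interior_plantable",
    "make_fixture_db",
    "write_fasta",
]

_RESIDUE_ORDER = tuple(sorted(STANDARD_RESIDUES))

ACTIVITY_POOL = (
    "ACE-inhibitory",
    "antihypertensive",
    "antimicrobial",
    "antioxidant",
    "antithrombotic",
    "DPP-IV-inhibitory",
    "immunomodulatory",
    "opioid",
)


def _default_composition() -> dict:
    # K+R at 5.5% each; the remaining 18 residues share the rest uniformly.
    boosted = 0.055
    rest = (1.0 - 2 * boosted) / 18.0
    return {aa: (boosted if aa in "KR" else rest) for aa in _RESIDUE_ORDER}


DEFAULT_COMPOSITION = _default_composition()


class PlantingError(RuntimeError):
    """A peptide cannot be released by the enzyme, or planting retries ran out."""


@dataclass
class PlantManifest:
    """Ground truth for planted peptides: where each landed and at which level."""

    rows: list = field(default_factory=list)
    # rows of dicts: peptide, protein_id, start, end, enzyme_id, expected_level

    def append(self, **row):
        self.rows.append(row)

    def __len__(self):
        return len(self.rows)

    def save(self, path):
        cols = ["peptide", "protein_id", "start", "end", "enzyme_id", "expected_level"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def _validate_composition(composition: dict) -> tuple:
    residues = tuple(sorted(composition))
    if set(residues) != STANDARD_RESIDUES:
        raise ValueError("composition must cover exactly the 20 standard residues")
    probs = np.array([composition[aa] for aa in residues], dtype=float)
    if (probs < 0).any():
        raise ValueError("composition probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1 (got {probs.sum():.12f})")
    return residues, probs


def random_proteome(
    n_proteins: int,
    length_mean: float = 250.0,
    length_sd: float = 75.0,
    composition: dict | None = None,
    seed: int = 0,
) -> list:
    """Draw ``n_proteins`` random proteins (ids SYN_000001, ...).

    Lengths are normal(length_mean, length_sd) rounded and clipped at 2.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    residues, probs = _validate_composition(composition or DEFAULT_COMPOSITION)
    rng = np.random.default_rng(seed)
    lengths = np.maximum(2, np.rint(rng.normal(length_mean, length_sd, n_proteins)).astype(int))
    proteins = []
    for i, L in enumerate(lengths, start=1):
        seq = "".join(rng.choice(residues, size=int(L), p=probs))
        proteins.append(ProteinRecord(f"SYN_{i:06d}", seq, "synthetic protein"))
    return proteins


def write_fasta(proteins: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in proteins:
            header = f">{p.protein_id}"
            if p.description:
                header += f" {p.description}"
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def releasable(peptide: str, rule: CleavageRule, max_level: int) -> bool:
    """Whether the enzyme can release ``peptide`` at some level <= max_level.

    The binding constraint is internal: every cleavage site inside the bare
    peptide is a forced miscleavage of the released product.
    """
    if len(peptide) < 2:
        return False
    return len(find_cleavage_sites(peptide, rule)) <= max_level


def _context_bg(rule: CleavageRule) -> str:
    """A residue whose homopolymer the enzyme never cuts (context filler)."""
    for aa in "GSANQTPHRKDEWYCMVLIF":
        if not find_cleavage_sites(aa * 12, rule):
            return aa
    raise PlantingError(f"no inert background residue for enzyme {rule.enzyme_id}")


def _left_context(rule: CleavageRule, first_res: str, bg: str):
    """Shortest flank c with a cleaved boundary between c and ``first_res``."""
    for length in (1, 2):
        for combo in itertools.product(_RESIDUE_ORDER, repeat=length):
            ctx = "".join(combo)
            probe = bg * 4 + ctx + first_res + bg * 4
            if is_cleavage_boundary(probe, 4 + length, rule):
                return ctx
    return None


def _right_context(rule: CleavageRule, last_res: str, bg: str):
    """Shortest flank c with a cleaved boundary between ``last_res`` and c."""
    for length in (1, 2):
        for combo in itertools.product(_RESIDUE_ORDER, repeat=length):
            ctx = "".join(combo)
            probe = bg * 4 + last_res + ctx + bg * 4
            if is_cleavage_boundary(probe, 5, rule):
                return ctx
    return None


def interior_plantable(peptide: str, rule: CleavageRule) -> bool:
    """Whether flank contexts exist on *both* sides of the peptide.

    Peptides failing this can still be planted, but only against a protein
    terminus (at most one N- and one C-terminal plant per protein), so bulk
    planting prefers interior-plantable peptides.
    """
    if not peptide:
        return False
    bg = _context_bg(rule)
    return (
        _cached_left_context(rule, peptide[0], bg) is not None
        and _cached_right_context(rule, peptide[-1], bg) is not None
    )


_CTX_CACHE: dict = {}


def _cached_left_context(rule, res, bg):
    key = ("L", rule.enzyme_id, id(rule), res, bg)
    if key not in _CTX_CACHE:
        _CTX_CACHE[key] = _left_context(rule, res, bg)
    return _CTX_CACHE[key]


def _cached_right_context(rule, res, bg):
    key = ("R", rule.enzyme_id, id(rule), res, bg)
    if key not in _CTX_CACHE:
        _CTX_CACHE[key] = _right_context(rule, res, bg)
    return _CTX_CACHE[key]


def _verify_release(sequence: str, start: int, end: int, peptide: str, rule: CleavageRule):
    """Release check against the site oracle; returns observed level or None.

    ``start``/``end`` are 1-based inclusive.  The span must reproduce the
    peptide, have cleavage boundaries (or a terminus) at both ends, and the
    observed level is the number of cleaved boundaries strictly inside.
    """
    if sequence[start - 1 : end] != peptide:
        return None
    sites = set(find_cleavage_sites(sequence, rule))
    left_ok = start == 1 or (start - 1) in sites
    right_ok = end == len(sequence) or end in sites
    if not (left_ok and right_ok):
        return None
    return sum(1 for s in sites if start <= s <= end - 1)


def plant_peptides(
    proteome: Sequence[ProteinRecord],
    peptides: Sequence[str],
    enzyme_id: str,
    max_level: int = 0,
    seed: int = 0,
    ruleset=None,
    max_retries: int = 100,
):
    """Insert peptides so the enzyme releases each at a level <= max_level.

    Returns (modified proteome, PlantManifest).  Each insertion is verified
    against the cleavage-site oracle and re-drawn on failure, up to
    ``max_retries`` per peptide; exhaustion is an error, never a silent skip.
    """
    from .rules import load_builtin_rules  # local import to avoid cycle noise

    ruleset = ruleset if ruleset is not None else load_builtin_rules()
    rule = ruleset.get(enzyme_id)
    rng = np.random.default_rng(seed)
    sequences = [p.sequence for p in proteome]
    if not sequences:
        raise ValueError("empty proteome")
    # Occupied spans per protein (start, end), with margin, to keep plants apart.
    occupied: dict = {i: [] for i in range(len(sequences))}
    used_cterm: set = set()
    used_nterm: set = set()
    manifest = PlantManifest()
    bg = _context_bg(rule)

    for peptide in peptides:
        peptide = peptide.upper()
        if set(peptide) - STANDARD_RESIDUES:
            raise PlantingError(f"peptide {peptide!r} has non-standard residues")
        if not releasable(peptide, rule, max_level):
            raise PlantingError(
                f"peptide {peptide!r} cannot be released by {enzyme_id} "
                f"within {max_level} miscleavage(s)"
            )
        lctx = _cached_left_context(rule, peptide[0], bg)
        rctx = _cached_right_context(rule, peptide[-1], bg)
        placed = False
        for _ in range(max_retries):
            pi = int(rng.integers(len(sequences)))
            seq = sequences[pi]
            if lctx is None and rctx is None:
                break  # must own both termini: emit as its own protein below
            if lctx is None:
                if pi in used_nterm:
                    continue
                pos = 0
            elif rctx is None:
                if pi in used_cterm:
                    continue
                pos = len(seq)
            else:
                pos = int(rng.integers(0, len(seq) + 1))
            margin = 5
            lo = pos - margin
            hi = pos + len(lctx or "") + len(peptide) + len(rctx or "") + margin
            if any(s - margin < hi and lo < e + margin for s, e in occupied[pi]):
                continue
            insert = (lctx or "") + peptide + (rctx or "")
            candidate = seq[:pos] + insert + seq[pos:]
            start = pos + len(lctx or "") + 1
            end = start + len(peptide) - 1
            level = _verify_release(candidate, start, end, peptide, rule)
            if level is None or level > max_level:
                continue
            # Shift previously recorded plants in this protein that sit
            # downstream of the insertion point.
            pid = proteome[pi].protein_id
            for row in manifest.rows:
                if row["protein_id"] == pid and row["start"] > pos:
                    row["start"] += len(insert)
                    row["end"] += len(insert)
            occupied[pi] = [
                (s + len(insert), e + len(insert)) if s > pos else (s, e)
                for s, e in occupied[pi]
            ]
            occupied[pi].append((start, end))
            sequences[pi] = candidate
            if lctx is None:
                used_nterm.add(pi)
            if rctx is None:
                used_cterm.add(pi)
            manifest.append(
                peptide=peptide,
                protein_id=pid,
                start=start,
                end=end,
                enzyme_id=enzyme_id,
                expected_level=level,
            )
            placed = True
            break
        if not placed:
            if lctx is None and rctx is None:
                # No flank can create either boundary: the peptide must span a
                # whole protein.  Append it as an extra synthetic protein.
                level = len(find_cleavage_sites(peptide, rule))
                pid = f"SYN_P{len(sequences) + 1:05d}"
                sequences.append(peptide)
                proteome = list(proteome) + [
                    ProteinRecord(pid, peptide, "planted whole-protein peptide")
                ]
                occupied[len(sequences) - 1] = [(1, len(peptide))]
                manifest.append(
                    peptide=peptide,
                    protein_id=pid,
                    start=1,
                    end=len(peptide),
                    enzyme_id=enzyme_id,
                    expected_level=level,
                )
            else:
                raise PlantingError(
                    f"could not place peptide {peptide!r} after {max_retries} retries"
                )
    modified = [
        ProteinRecord(p.protein_id, sequences[i], p.description)
        for i, p in enumerate(proteome)
    ]
    return modified, manifest


def _random_peptide(rng, length: int, avoid: set) -> str:
    for _ in range(1000):
        seq = "".join(rng.choice(_RESIDUE_ORDER, size=length))
        if seq not in avoid:
            return seq
    raise RuntimeError("could not draw a fresh peptide sequence")


def make_fixture_db(
    counts: dict | None = None,
    seed: int = 0,
    n_sources: int = 3,
    n_overlap: int = 3,
    out=None,
) -> BioactiveDB:
    """Deterministic fixture database across >= 3 pseudo-sources.

    ``counts`` gives entries per length group, default
    {"very_short": 80, "short": 100, "long": 25}; ``n_overlap`` sequences
    are duplicated into a second source (with another activity) to exercise
    merge-union.  Same seed, same file.
    """
    if counts is None:
        counts = {"very_short": 80, "short": 100, "long": 25}
    if n_sources < 3:
        raise ValueError("fixture requires >= 3 pseudo-sources")
    rng = np.random.default_rng(seed)
    length_choices = {
        "very_short": (2, 3),
        "short": tuple(range(4, 30)),
        "long": tuple(range(30, 46)),
    }
    sequences: list = []
    seen: set = set()
    for group in ("very_short", "short", "long"):
        for _ in range(int(counts.get(group, 0))):
            L = int(rng.choice(length_choices[group]))
            seq = _random_peptide(rng, L, seen)
            seen.add(seq)
            sequences.append(seq)
    if not sequences:
        raise ValueError("fixture spec yields no sequences")
    source_names = [f"SRC_{chr(ord('A') + i)}" for i in range(n_sources)]
    per_source: dict = {name: [] for name in source_names}
    for k, seq in enumerate(sequences):
        name = source_names[int(rng.integers(n_sources))]
        activity = ACTIVITY_POOL[int(rng.integers(len(ACTIVITY_POOL)))]
        per_source[name].append((seq, activity, f"{name.lower()}-{k + 1:04d}"))
    # Overlap: copy a few sequences into a different source under a new id.
    overlap_pool = [s for s in sequences][: max(0, n_overlap)]
    for k, seq in enumerate(overlap_pool):
        home = next(name for name, recs in per_source.items() if any(r[0] == seq for r in recs))
        other = source_names[(source_names.index(home) + 1) % n_sources]
        activity = ACTIVITY_POOL[int(rng.integers(len(ACTIVITY_POOL)))]
        per_source[other].append((seq, activity, f"{other.lower()}-x{k + 1:03d}"))
    ingests = [
        IngestResult(name, sorted(per_source[name]), []) for name in source_names
    ]
    db = merge_sources(ingests)
    db.metadata["seed"] = str(seed)
    if out is not None:
        save_db(db, out)
    return db
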