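"""Declarative protease cleavage-rule model and built-in enzyme table.

A protease's specificity is expressed over the Schechter–Berger context
window around a candidate cleavage boundary: positions P4..P1 on the
N-terminal side and P1'..P2' on the C-terminal side, with cleavage occurring
between P1 and P1'.  A :class:`CleavageRule` is an ordered table of
:class:`RuleClause` entries, each either a ``cleave`` or a ``block`` clause
with a priority; among the clauses whose residue constraints all match the
boundary context, the highest-priority one decides.  No matching clause
means no cleavage.

This three-level priority scheme (base rule < exception < exception-to-
exception) formalizes the rule/exception prose of the ExPASy PeptideCutter
documentation, e.g. trypsin cleaves after K or R, not before P, except in
the WK|P and MR|P contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "STANDARD_RESIDUES",
    "AMBIGUOUS_RESIDUES",
    "VALID_RESIDUES",
    "CONTEXT_POSITIONS",
    "RuleClause",
    "CleavageRule",
    "RuleSet",
    "RuleError",
    "UnknownEnzymeError",
    "load_builtin_rules",
    "is_cleavage_boundary",
    "find_cleavage_sites",
    "register_rule",
    "load_rule_tsv",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity/rare codes tolerated in input sequences.  A clause constraining a
#: position that holds one of these never matches, so no cleavage decision is
#: ever based on an ambiguous residue (fail-safe toward fewer cleavages).
AMBIGUOUS_RESIDUES = frozenset("BJZXUO")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES

#: Context positions, N- to C-terminal.  For a boundary at 1-based index i
#: (between residues i and i+1), P1 is residue i and P1' is residue i+1.
CONTEXT_POSITIONS = ("P4", "P3", "P2", "P1", "P1p", "P2p")

# 0-based sequence index of each context position relative to boundary i:
# index = i + offset  (P1 -> i-1 in 0-based terms, P1' -> i, ...)
_OFFSETS = {"P4": -4, "P3": -3, "P2": -2, "P1": -1, "P1p": 0, "P2p": 1}

# Constraint evaluation order: cheapest discriminators first.
_EVAL_ORDER = ("P1", "P1p", "P2", "P2p", "P3", "P4")


class RuleError(ValueError):
    """Invalid clause, clause table, or rule registration."""


class UnknownEnzymeError(KeyError):
    """Lookup of an enzyme_id not present in the RuleSet."""


@dataclass(frozen=True)
class RuleClause:
    """One cleave/block clause over a partial P4..P2' residue context.

    ``constraints`` maps context positions to the residue sets they must
    hold; unconstrained positions are absent.  A clause matches a boundary
    only if every constrained position falls inside the sequence and holds
    a residue from its set.
    """

    polarity: str  # "cleave" | "block"
    priority: int
    constraints: Mapping[str, frozenset]

    def __post_init__(self):
        if self.polarity not in ("cleave", "block"):
            raise RuleError(f"polarity must be 'cleave' or 'block', got {self.polarity!r}")
        if not isinstance(self.priority, int) or self.priority < 1:
            raise RuleError(f"priority must be a positive integer, got {self.priority!r}")
        if not self.constraints:
            raise RuleError("clause constrains no position")
        frozen = {}
        for pos, residues in dict(self.constraints).items():
            if pos not in CONTEXT_POSITIONS:
                raise RuleError(f"unknown context position {pos!r}")
            rset = frozenset(residues)
            if not rset:
                raise RuleError(f"empty residue set at {pos}")
            bad = rset - STANDARD_RESIDUES
            if bad:
                raise RuleError(f"non-standard residues {sorted(bad)} at {pos}")
            frozen[pos] = rset
        object.__setattr__(self, "constraints", frozen)

    def matches(self, sequence: str, boundary: int) -> bool:
        """True if every constrained position is in-window and satisfied."""
        L = len(sequence)
        for pos, residues in self.constraints.items():
            idx = boundary + _OFFSETS[pos]
            if idx < 0 or idx >= L or sequence[idx] not in residues:
                return False
        return True

    def describe(self) -> str:
        parts = ",".join(
            f"{p}={''.join(sorted(self.constraints[p]))}"
            for p in CONTEXT_POSITIONS
            if p in self.constraints
        )
        return f"{self.polarity}@{self.priority}[{parts}]"


def _clauses_conflict(a: RuleClause, b: RuleClause) -> bool:
    """Whether two same-priority, opposite-polarity clauses can both match.

    They can iff, at every position constrained by either clause, the residue
    sets intersect (an unconstrained position admits any residue).
    """
    for pos in CONTEXT_POSITIONS:
        sa = a.constraints.get(pos, STANDARD_RESIDUES)
        sb = b.constraints.get(pos, STANDARD_RESIDUES)
        if not (sa & sb):
            return False
    return True


@dataclass(frozen=True)
class CleavageRule:
    """Ordered clause table for one enzyme.  Default decision: no cleavage."""

    enzyme_id: str
    display_name: str
    clauses: tuple

    def __post_init__(self):
        eid = self.enzyme_id
        if not eid or eid != eid.lower() or any(c.isspace() for c in eid):
            raise RuleError(f"enzyme_id must be a lowercase whitespace-free token, got {eid!r}")
        clauses = tuple(self.clauses)
        if not clauses:
            raise RuleError(f"{eid}: empty clause table")
        object.__setattr__(self, "clauses", clauses)
        self.validate()
        # Evaluation plan: clauses sorted by descending priority, constraints
        # in cheap-first order.  Post-validation, the first matching clause in
        # this order decides the boundary.
        plan = []
        for cl in sorted(clauses, key=lambda c: (-c.priority, c.polarity)):
            checks = tuple(
                (_OFFSETS[p], cl.constraints[p]) for p in _EVAL_ORDER if p in cl.constraints
            )
            plan.append((cl.polarity == "cleave", checks))
        object.__setattr__(self, "_plan", tuple(plan))

    def validate(self) -> None:
        """Reject same-priority opposite-polarity clauses that can co-match."""
        by_priority: dict = {}
        for cl in self.clauses:
            by_priority.setdefault(cl.priority, []).append(cl)
        for prio, group in by_priority.items():
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    if a.polarity != b.polarity and _clauses_conflict(a, b):
                        raise RuleError(
                            f"enzyme {self.enzyme_id!r}: ambiguous priority-{prio} clauses "
                            f"{a.describe()} vs {b.describe()}"
                        )


@dataclass(frozen=True)
class RuleSet:
    """Immutable enzyme_id -> CleavageRule table with provenance note."""

    rules: Mapping[str, CleavageRule]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rules", dict(self.rules))

    def __contains__(self, enzyme_id: str) -> bool:
        return enzyme_id in self.rules

    def __len__(self) -> int:
        return len(self.rules)

    def enzyme_ids(self):
        return sorted(self.rules)

    def get(self, enzyme_id: str) -> CleavageRule:
        try:
            return self.rules[enzyme_id]
        except KeyError:
            raise UnknownEnzymeError(
                f"unknown enzyme {enzyme_id!r}; known: {', '.join(sorted(self.rules))}"
            ) from None


def _clause(polarity: str, priority: int, **constraints: str) -> RuleClause:
    return RuleClause(polarity, priority, {p: frozenset(r) for p, r in constraints.items()})


def _not(residues: str) -> str:
    return "".join(sorted(STANDARD_RESIDUES - set(residues)))


def _builtin_table() -> dict:
    """Clause tables for the 15 default enzymes, after ExPASy PeptideCutter.

    Priorities: 1 = base specificity, 2 = exception (e.g. proline block),
    3 = exception-to-exception (Keil contexts).
    """
    t = {}

    # Trypsin: after K/R; blocked by P at P1' except WK|P and MR|P; Keil
    # block triplets (CD)K|D, CK|(HY), CR|K, RR|(HR).
    t["trypsin"] = (
        "Trypsin",
        [
            _clause("cleave", 1, P1="KR"),
            _clause("block", 2, P1p="P"),
            _clause("cleave", 3, P2="W", P1="K", P1p="P"),
            _clause("cleave", 3, P2="M", P1="R", P1p="P"),
            _clause("block", 3, P2="CD", P1="K", P1p="D"),
            _clause("block", 3, P2="C", P1="K", P1p="HY"),
            _clause("block", 3, P2="C", P1="R", P1p="K"),
            _clause("block", 3, P2="R", P1="R", P1p="HR"),
        ],
    )
    t["chymotrypsin-high"] = (
        "Chymotrypsin (high specificity)",
        [
            _clause("cleave", 1, P1="FYW"),
            _clause("block", 2, P1p="P"),
            _clause("block", 2, P1="W", P1p="M"),
        ],
    )
    t["chymotrypsin-low"] = (
        "Chymotrypsin (low specificity)",
        [
            _clause("cleave", 1, P1="FLYWMH"),
            _clause("block", 2, P1p="P"),
            _clause("block", 2, P1="W", P1p="M"),
            _clause("block", 2, P1="M", P1p="Y"),
            _clause("block", 2, P1="H", P1p="DMW"),
        ],
    )
    # Pepsin: cleaves around F/L (pH 1.3) or F/L/W/Y (pH > 2); the P3/P2/P2'
    # side constraints follow the PeptideCutter table.
    for eid, name, hydrophobic in (
        ("pepsin-ph1.3", "Pepsin (pH 1.3)", "FL"),
        ("pepsin-ph2.0", "Pepsin (pH > 2)", "FLWY"),
    ):
        t[eid] = (
            name,
            [
                _clause(
                    "cleave", 1,
                    P3=_not("HKR"), P2=_not("P"), P1=_not("R"),
                    P1p=hydrophobic, P2p=_not("P"),
                ),
                _clause(
                    "cleave", 1,
                    P3=_not("HKR"), P2=_not("P"), P1=hydrophobic,
                    P1p="".join(sorted(STANDARD_RESIDUES)), P2p=_not("P"),
                ),
            ],
        )
    t["thermolysin"] = (
        "Thermolysin",
        [_clause("cleave", 1, P1=_not("DE"), P1p="AFILMV", P2p=_not("P"))],
    )
    t["lys-c"] = ("Lys-C", [_clause("cleave", 1, P1="K")])
    t["lys-n"] = ("Lys-N", [_clause("cleave", 1, P1p="K")])
    t["arg-c"] = ("Arg-C proteinase", [_clause("cleave", 1, P1="R")])
    t["asp-n"] = ("Asp-N endopeptidase", [_clause("cleave", 1, P1p="D")])
    t["glu-c"] = ("Glu-C (Glutamyl endopeptidase)", [_clause("cleave", 1, P1="E")])
    t["proteinase-k"] = ("Proteinase K", [_clause("cleave", 1, P1="AEFILTVWY")])
    t["clostripain"] = ("Clostripain", [_clause("cleave", 1, P1="R")])
    t["enterokinase"] = (
        "Enterokinase",
        [_clause("cleave", 1, P4="DE", P3="DE", P2="DE", P1="K")],
    )
    t["factor-xa"] = (
        "Factor Xa",
        [_clause("cleave", 1, P4="AFGILTVM", P3="DE", P2="G", P1="R")],
    )
    return t


def load_builtin_rules() -> RuleSet:
    """Build the 15-enzyme default RuleSet (pure function, deterministic)."""
    rules = {}
    for eid, (name, clauses) in _builtin_table().items():
        rules[eid] = CleavageRule(eid, name, tuple(clauses))
    return RuleSet(rules, provenance="built-in tables after ExPASy PeptideCutter")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")


def is_cleavage_boundary(sequence: str, i: int, rule: CleavageRule) -> bool:
    """Decide boundary i (1-based; between residues i and i+1).

    Highest-priority matching clause decides; no match means no cleavage.
    """
    _check_sequence(sequence)
    if not 1 <= i <= len(sequence) - 1:
        raise IndexError(f"boundary {i} outside 1..{len(sequence) - 1}")
    seq = sequence
    L = len(seq)
    for is_cleave, checks in rule._plan:
        for off, residues in checks:
            idx = i + off
            if idx < 0 or idx >= L or seq[idx] not in residues:
                break
        else:
            return is_cleave
    return False


def find_cleavage_sites(sequence: str, rule: CleavageRule) -> list:
    """All cleaved boundaries of ``sequence`` under ``rule``, ascending.

    The C-terminal end of the protein is never reported as a boundary.
    """
    _check_sequence(sequence)
    L = len(sequence)
    plan = rule._plan
    sites = []
    for i in range(1, L):
        for is_cleave, checks in plan:
            for off, residues in checks:
                idx = i + off
                if idx < 0 or idx >= L or sequence[idx] not in residues:
                    break
            else:
                if is_cleave:
                    sites.append(i)
                break
    return sites


def register_rule(ruleset: RuleSet, rule: CleavageRule, overwrite: bool = False) -> RuleSet:
    """Return a new RuleSet including ``rule``; the original is unmodified."""
    if rule.enzyme_id in ruleset.rules and not overwrite:
        raise RuleError(f"enzyme {rule.enzyme_id!r} already registered (pass overwrite=True)")
    rules = dict(ruleset.rules)
    rules[rule.enzyme_id] = rule
    return RuleSet(rules, provenance=ruleset.provenance)


_TSV_COLUMNS = ["enzyme_id", "priority", "polarity", "P4", "P3", "P2", "P1", "P1p", "P2p"]


def load_rule_tsv(path, base: RuleSet | None = None, overwrite: bool = False) -> RuleSet:
    """Merge a user rule table (TSV) into ``base`` (default: built-ins).

    Columns: enzyme_id, priority, polarity, P4, P3, P2, P1, P1p, P2p; residue
    sets are bare strings and "-" marks an unconstrained position.
    """
    ruleset = base if base is not None else load_builtin_rules()
    clauses_by_enzyme: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise RuleError(f"rule TSV header must be {_TSV_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise RuleError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            eid, prio, polarity = fields[0], fields[1], fields[2]
            constraints = {
                pos: frozenset(val)
                for pos, val in zip(CONTEXT_POSITIONS, fields[3:])
                if val != "-"
            }
            try:
                clause = RuleClause(polarity, int(prio), constraints)
            except (RuleError, ValueError) as exc:
                raise RuleError(f"{path}:{lineno}: {exc}") from exc
            clauses_by_enzyme.setdefault(eid, []).append(clause)
    for eid, clauses in clauses_by_enzyme.items():
        rule = CleavageRule(eid, eid, tuple(clauses))
        ruleset = register_rule(ruleset, rule, overwrite=overwrite)
    return ruleset
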