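"""Cleavage-rule engine: clause semantics, built-in table, oracle equivalence."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from pepdig import (
    CleavageRule,
    RuleClause,
    RuleError,
    UnknownEnzymeError,
    find_cleavage_sites,
    is_cleavage_boundary,
    load_builtin_rules,
    load_rule_tsv,
    register_rule,
)
from conftest import STANDARD, random_sequence

_OFFSETS = {"P4": -4, "P3": -3, "P2": -2, "P1": -1, "P1p": 0, "P2p": 1}


def oracle_boundary(sequence, i, rule):
    """Brute-force per-boundary decision straight from the clause table."""
    best = None
    for clause in rule.clauses:
        ok = True
        for pos, residues in clause.constraints.items():
            idx = i + _OFFSETS[pos]
            if idx < 0 or idx >= len(sequence) or sequence[idx] not in residues:
                ok = False
                break
        if ok and (best is None or clause.priority > best.priority):
            best = clause
    return best is not None and best.polarity == "cleave"


def oracle_sites(sequence, rule):
    return [i for i in range(1, len(sequence)) if oracle_boundary(sequence, i, rule)]


class TestBuiltinTable:
    def test_fifteen_enzymes_with_named_defaults(self, ruleset):
        assert len(ruleset) == 15
        assert "trypsin" in ruleset and "thermolysin" in ruleset

    def test_pure_function(self):
        a, b = load_builtin_rules(), load_builtin_rules()
        assert a.enzyme_ids() == b.enzyme_ids()
        for eid in a.enzyme_ids():
            assert a.get(eid).clauses == b.get(eid).clauses

    def test_unknown_enzyme_is_an_error(self, ruleset):
        with pytest.raises(UnknownEnzymeError):
            ruleset.get("papain")

    def test_removing_kp_block_still_validates(self, trypsin):
        remaining = tuple(
            c for c in trypsin.clauses
            if not (c.polarity == "block" and c.priority == 2)
        )
        CleavageRule("trypsin-variant", "t", remaining)  # no exception raised


class TestTrypsinForcedCases:
    """The published trypsin behaviour: K/R rule, proline block, WK/MR overrides."""

    @pytest.mark.parametrize(
        "sequence,boundary,expected",
        [
            ("AAKAAA", 3, True),  # C-terminal of K
            ("AAKPAA", 3, False),  # proline block
            ("AWKPAA", 3, True),  # W at P2 overrides the block
            ("MRPAAA", 2, True),  # M at P2 overrides the block
        ],
    )
    def test_forced_cases(self, trypsin, sequence, boundary, expected):
        assert is_cleavage_boundary(sequence, boundary, trypsin) is expected

    @pytest.mark.parametrize(
        "sequence,boundary",
        [("ACKDAA", 3), ("ADKDAA", 3), ("ACKHAA", 3), ("ACKYAA", 3),
         ("ACRKAA", 3), ("ARRHAA", 3), ("ARRRAA", 3)],
    )
    def test_keil_block_triplets(self, trypsin, sequence, boundary):
        assert not is_cleavage_boundary(sequence, boundary, trypsin)

    def test_every_trypsin_site_has_k_or_r_at_p1(self, trypsin, rng):
        for _ in range(300):
            seq = random_sequence(rng)
            for i in find_cleavage_sites(seq, trypsin):
                assert seq[i - 1] in "KR"


class TestFindSites:
    def test_two_forced_k_sites(self, trypsin):
        assert find_cleavage_sites("AAKAAKAA", trypsin) == [3, 6]

    def test_no_basic_residues_no_sites(self, trypsin):
        assert find_cleavage_sites("AAAAAA", trypsin) == []

    def test_boundary_index_bounds(self, trypsin):
        with pytest.raises(IndexError):
            is_cleavage_boundary("AAKAAA", 0, trypsin)
        with pytest.raises(IndexError):
            is_cleavage_boundary("AAKAAA", 6, trypsin)

    def test_thermolysin_matches_bruteforce(self, ruleset, rng):
        rule = ruleset.get("thermolysin")
        assert find_cleavage_sites("GGLGGAGG", rule) == oracle_sites("GGLGGAGG", rule)
        for _ in range(200):
            seq = random_sequence(rng)
            assert find_cleavage_sites(seq, rule) == oracle_sites(seq, rule)

    def test_all_enzymes_match_bruteforce_oracle(self, ruleset, rng):
        for eid in ruleset.enzyme_ids():
            rule = ruleset.get(eid)
            for _ in range(150):
                seq = random_sequence(rng)
                assert find_cleavage_sites(seq, rule) == oracle_sites(seq, rule), (eid, seq)

    def test_ambiguous_residues_never_cleaved(self, trypsin):
        # B/X at P1 carry no decision; K before X still cleaves (P1' unconstrained
        # by the base clause), K before P stays blocked.
        assert find_cleavage_sites("AABXAA", trypsin) == []
        assert find_cleavage_sites("AAKXAA", trypsin) == [3]


class TestPyteomicsCrossCheck:
    """Independent transcription of the same published specificity tables."""

    MAPPING = {
        "chymotrypsin-high": "chymotrypsin high specificity",
        "chymotrypsin-low": "chymotrypsin low specificity",
        "pepsin-ph1.3": "pepsin ph1.3",
        "pepsin-ph2.0": "pepsin ph2.0",
        "thermolysin": "thermolysin",
        "lys-c": "lysc",
        "arg-c": "arg-c",
        "asp-n": "asp-n",
        "glu-c": "glutamyl endopeptidase",
        "proteinase-k": "proteinase k",
        "clostripain": "clostripain",
        "enterokinase": "enterokinase",
        "factor-xa": "factor xa",
    }

    @staticmethod
    def regex_sites(seq, pattern):
        return sorted(m.end() for m in re.finditer(pattern, seq) if 0 < m.end() < len(seq))

    def test_against_expasy_regexes(self, ruleset, rng):
        parser = pytest.importorskip("pyteomics.parser")
        for eid, key in self.MAPPING.items():
            rule = ruleset.get(eid)
            for _ in range(150):
                seq = random_sequence(rng)
                assert find_cleavage_sites(seq, rule) == self.regex_sites(
                    seq, parser.expasy_rules[key]
                ), (eid, seq)

    def test_trypsin_is_base_rule_minus_exceptions(self, ruleset, rng):
        parser = pytest.importorskip("pyteomics.parser")
        rule = ruleset.get("trypsin")
        for _ in range(300):
            seq = random_sequence(rng)
            expected = sorted(
                set(self.regex_sites(seq, parser.expasy_rules["trypsin"]))
                - set(self.regex_sites(seq, parser.expasy_rules["trypsin_exception"]))
            )
            assert find_cleavage_sites(seq, rule) == expected, seq


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet=STANDARD, min_size=12, max_size=40),
    data=st.data(),
)
def test_context_locality(seq, data):
    """Mutating a residue > 4 positions from a boundary never changes it."""
    ruleset = load_builtin_rules()
    eid = data.draw(st.sampled_from(ruleset.enzyme_ids()))
    rule = ruleset.get(eid)
    i = data.draw(st.integers(min_value=5, max_value=len(seq) - 5))
    far = data.draw(
        st.integers(min_value=0, max_value=len(seq) - 1).filter(lambda j: abs(j - (i - 1)) > 4 and abs(j - i) > 4)
    )
    mutant = seq[:far] + data.draw(st.sampled_from(STANDARD)) + seq[far + 1 :]
    assert is_cleavage_boundary(seq, i, rule) == is_cleavage_boundary(mutant, i, rule)


class TestValidationAndRegistration:
    def test_conflicting_same_priority_clauses_rejected(self):
        clauses = (
            RuleClause("cleave", 1, {"P1": frozenset("K")}),
            RuleClause("block", 1, {"P1p": frozenset("A")}),
        )
        with pytest.raises(RuleError, match="ambiguous"):
            CleavageRule("bad", "bad", clauses)

    def test_disjoint_same_priority_clauses_accepted(self):
        clauses = (
            RuleClause("cleave", 1, {"P1": frozenset("K")}),
            RuleClause("block", 1, {"P1": frozenset("R")}),
        )
        CleavageRule("ok", "ok", clauses)

    def test_register_new_enzyme_and_use_it(self, ruleset):
        gluc = CleavageRule(
            "gluc-custom",
            "Glu-C with proline block",
            (
                RuleClause("cleave", 1, {"P1": frozenset("E")}),
                RuleClause("block", 2, {"P1p": frozenset("P")}),
            ),
        )
        extended = register_rule(ruleset, gluc)
        assert find_cleavage_sites("AAEAAA", extended.get("gluc-custom")) == [3]
        assert "gluc-custom" not in ruleset  # value semantics

    def test_register_duplicate_without_overwrite(self, ruleset, trypsin):
        with pytest.raises(RuleError, match="already registered"):
            register_rule(ruleset, trypsin)
        register_rule(ruleset, trypsin, overwrite=True)

    def test_empty_clause_table_rejected(self):
        with pytest.raises(RuleError):
            CleavageRule("empty", "empty", ())

    def test_clause_rejects_bad_inputs(self):
        with pytest.raises(RuleError):
            RuleClause("cleave", 1, {})
        with pytest.raises(RuleError):
            RuleClause("cleave", 1, {"P1": frozenset()})
        with pytest.raises(RuleError):
            RuleClause("cleave", 1, {"P9": frozenset("K")})
        with pytest.raises(RuleError):
            RuleClause("maybe", 1, {"P1": frozenset("K")})


class TestRuleTsv:
    def test_load_and_merge_user_rules(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text(
            "enzyme_id\tpriority\tpolarity\tP4\tP3\tP2\tP1\tP1p\tP2p\n"
            "gluc\t1\tcleave\t-\t-\t-\tE\t-\t-\n"
            "gluc\t2\tblock\t-\t-\t-\t-\tP\t-\n"
        )
        ruleset = load_rule_tsv(path)
        assert len(ruleset) == 16
        assert find_cleavage_sites("AAEAAA", ruleset.get("gluc")) == [3]
        assert find_cleavage_sites("AAEPAA", ruleset.get("gluc")) == []

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text("enzyme\tprio\n")
        with pytest.raises(RuleError, match="header"):
            load_rule_tsv(path)
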