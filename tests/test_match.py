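"""Matching: containment semantics, oracle completeness, reports, exports."""

import pandas as pd
import pytest

from pepdig import (
    NonRedundantPeptide,
    ProteinRecord,
    backtrack,
    build_match_index,
    counts_grid,
    digest_collection,
    export_list_all,
    match_peptides,
    merge_sources,
    summarize,
)
from pepdig.bpdb import IngestResult


def make_db(seq_to_activity):
    records = [(s, a, f"r{i}") for i, (s, a) in enumerate(seq_to_activity.items())]
    return merge_sources([IngestResult("DB", records, [])])


def pep(seq, enzyme="trypsin", level=0, occurrences=None):
    return NonRedundantPeptide(seq, enzyme, level, occurrences or [("P1", 1, len(seq))])


class TestIndex:
    def test_exact_lookup(self):
        index = build_match_index(make_db({"FK": "ace", "IPP": "amp"}))
        assert index.exact("FK") is not None
        assert index.exact("KF") is None

    def test_scan_finds_contained_entry(self):
        index = build_match_index(make_db({"FK": "ace", "IPP": "amp"}))
        hits = list(index.scan("AFKA"))
        assert [(e.sequence, start) for e, start in hits] == [("FK", 1)]

    def test_scan_equals_naive_all_pairs(self, rng):
        patterns = {
            "".join(rng.choice("ACDEF") for _ in range(rng.randint(2, 6))): "act"
            for _ in range(120)
        }
        index = build_match_index(make_db(patterns))
        for _ in range(150):
            text = "".join(rng.choice("ACDEF") for _ in range(rng.randint(2, 40)))
            got = {(e.sequence, s) for e, s in index.scan(text)}
            expected = {
                (p, i)
                for p in patterns
                for i in range(len(text) - len(p) + 1)
                if text[i : i + len(p)] == p
            }
            assert got == expected


class TestMatchModes:
    def test_exact_equal(self):
        index = build_match_index(make_db({"FK": "ACE-inhibitory"}))
        records = match_peptides([pep("FK")], index, "exact")
        assert len(records) == 1
        assert records[0].hits[0].relation == "equal"
        assert records[0].activities() == ["ACE-inhibitory"]

    def test_peptide_containing_entry(self):
        index = build_match_index(make_db({"FK": "ace"}))
        assert match_peptides([pep("AFKA")], index, "exact") == []
        records = match_peptides([pep("AFKA")], index, "either")
        assert [h.relation for h in records[0].hits] == ["contains_subject"]
        assert records[0].hits[0].offset == 1

    def test_peptide_inside_entry(self):
        index = build_match_index(make_db({"AFKA": "antimicrobial"}))
        records = match_peptides([pep("FK")], index, "either")
        assert [h.relation for h in records[0].hits] == ["contained_in_subject"]
        assert records[0].hits[0].offset == 1

    def test_mode_monotonicity_and_oracle(self, rng):
        """either = exact ∪ query_covered ∪ subject_covered, and equals the
        quadratic all-pairs containment oracle."""
        db_seqs = {
            "".join(rng.choice("ACDEFG") for _ in range(rng.randint(2, 10))): "act"
            for _ in range(150)
        }
        index = build_match_index(make_db(db_seqs))
        peptides = [
            pep("".join(rng.choice("ACDEFG") for _ in range(rng.randint(2, 12))), level=i % 3)
            for i in range(400)
        ]
        by_mode = {
            mode: {r.peptide.key for r in match_peptides(peptides, index, mode)}
            for mode in ("exact", "query_covered", "subject_covered", "either")
        }
        assert by_mode["exact"] <= by_mode["query_covered"]
        assert by_mode["exact"] <= by_mode["subject_covered"]
        assert by_mode["either"] == by_mode["query_covered"] | by_mode["subject_covered"]
        oracle = set()
        for p in peptides:
            for s in db_seqs:
                if p.sequence in s or s in p.sequence:
                    oracle.add(p.key)
        assert by_mode["either"] == oracle

    def test_hit_soundness_by_direct_string_test(self, rng):
        db_seqs = {
            "".join(rng.choice("ACDE") for _ in range(rng.randint(2, 8))): "act"
            for _ in range(80)
        }
        index = build_match_index(make_db(db_seqs))
        peptides = [
            pep("".join(rng.choice("ACDE") for _ in range(rng.randint(2, 10))))
            for _ in range(200)
        ]
        for rec in match_peptides(peptides, index, "either"):
            for hit in rec.hits:
                q, s = rec.peptide.sequence, hit.entry.sequence
                if hit.relation == "equal":
                    assert q == s
                elif hit.relation == "contains_subject":
                    assert q[hit.offset : hit.offset + len(s)] == s and len(s) < len(q)
                else:
                    assert s[hit.offset : hit.offset + len(q)] == q and len(q) < len(s)

    def test_bad_mode(self):
        index = build_match_index(make_db({"FK": "ace"}))
        with pytest.raises(ValueError):
            match_peptides([pep("FK")], index, "fuzzy")


class TestReports:
    def test_backtrack_origin_format(self):
        index = build_match_index(make_db({"QK": "ace"}))
        peptide = pep("QK", occurrences=[("P1", 3, 4), ("P2", 7, 8), ("P1", 9, 10)])
        rows = backtrack(match_peptides([peptide], index, "either"))
        assert rows.loc[0, "origin_proteins"] == "P1,P2"
        assert rows.loc[0, "n_occurrences"] == 3
        single = backtrack(match_peptides([pep("QK")], index, "either"))
        assert single.loc[0, "origin_proteins"] == "P1"

    def test_row_count_equals_match_records(self, rng):
        index = build_match_index(make_db({"FK": "a", "QK": "b", "KK": "c"}))
        peptides = [pep(s, level=l) for s in ("FK", "QK", "KK", "GG") for l in (0, 1)]
        records = match_peptides(peptides, index, "either")
        assert len(backtrack(records)) == len(records)

    def test_summary_counts_di_peptide_example(self):
        """A protein yielding matched FK, QK (level 0) and KK (level 1) counts 3."""
        proteins = [ProteinRecord("SPLC1_S010010", "AFKAQKAKKA"), ProteinRecord("OTHER", "GGGG")]
        db = make_db({"FK": "ace", "QK": "ace", "KK": "ace"})
        index = build_match_index(db)
        peptides = [
            pep("FK", occurrences=[("SPLC1_S010010", 2, 3)]),
            pep("QK", occurrences=[("SPLC1_S010010", 5, 6)]),
            pep("KK", level=1, occurrences=[("SPLC1_S010010", 8, 9)]),
        ]
        records = match_peptides(peptides, index, "either")
        rows = summarize(records, proteins)
        by_id = rows.set_index("protein_id")
        assert by_id.loc["SPLC1_S010010", "n_bioactive_peptides"] == 3
        assert by_id.loc["OTHER", "n_bioactive_peptides"] == 0

    def test_summary_counts_multi_origin_once_per_origin(self):
        proteins = [ProteinRecord("P1", "AFKA"), ProteinRecord("P2", "GFKG")]
        index = build_match_index(make_db({"FK": "ace"}))
        peptide = pep("FK", occurrences=[("P1", 2, 3), ("P2", 2, 3)])
        records = match_peptides([peptide], index, "either")
        rows = summarize(records, proteins)
        assert rows["n_bioactive_peptides"].sum() == 2 >= len(records)


class TestExports:
    def test_counts_grid_percentage_formatting(self, ruleset):
        # the percentage column prints 2 decimals: 298/99905 -> "0.30"
        assert f"{100 * 298 / 99905:.2f}" == "0.30"
        proteins = [ProteinRecord("P1", "AFKAQKA")]
        result = digest_collection(proteins, ["trypsin"], 1, 2, ruleset)
        db = make_db({"AFK": "ace"})
        records = match_peptides(result.all_peptides(), build_match_index(db), "exact")
        grid = counts_grid(result, records)
        assert list(grid.columns) == [
            "enzyme", "miscleavage", "n_peptides", "n_bioactive", "bioactive_pct"
        ]
        assert set(grid["miscleavage"]) == {0, 1}
        row0 = grid[grid["miscleavage"] == 0].iloc[0]
        assert row0["n_bioactive"] == 1
        assert row0["bioactive_pct"] == f"{100 * 1 / row0['n_peptides']:.2f}"

    def test_csv_round_trip_and_empty(self, tmp_path):
        index = build_match_index(make_db({"FK": "ace"}))
        rows = backtrack(match_peptides([pep("FK")], index, "either"))
        path = tmp_path / "list_all.csv"
        export_list_all(rows, path)
        back = pd.read_csv(path)
        assert back.loc[0, "peptide"] == "FK"
        assert list(back.columns) == list(rows.columns)
        empty = backtrack([])
        export_list_all(empty, path)
        assert path.read_text().count("\n") == 1  # header only
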