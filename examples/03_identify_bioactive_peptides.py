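"""Identify bioactive peptides among digestion products.

Matching is at 100% identity with full query-or-subject coverage, i.e.
substring containment in either direction: a digested peptide hits a
database entry if the two are equal, the entry lies inside the peptide, or
the peptide lies inside the entry.
"""

from pepdig import (
    ProteinRecord,
    backtrack,
    build_match_index,
    digest_collection,
    match_peptides,
    merge_sources,
    summarize,
)
from pepdig.bpdb import IngestResult

db = merge_sources(
    [
        IngestResult(
            "DEMO",
            [
                ("FK", "ACE-inhibitory", "r1"),
                ("QK", "ACE-inhibitory", "r2"),
                ("KK", "antihypertensive", "r3"),
            ],
            [],
        )
    ]
)

proteins = [
    ProteinRecord("SPLC1_S010010", "AFKAQKAKKA"),  # carries FK, QK, and KK
    ProteinRecord("CONTROL", "GGGGGGGG"),
]
result = digest_collection(proteins, ["trypsin"], max_level=1)
matches = match_peptides(result.all_peptides(), build_match_index(db), mode="either")

print("list all (one row per matched peptide, enzyme, level):")
print(backtrack(matches).to_string(index=False))

print("\nsummary (one row per input protein):")
print(summarize(matches, proteins, result.all_peptides()).to_string(index=False))

# FK and QK are released at level 0, KK needs one missed cleavage; all three
# trace back to SPLC1_S010010 while the control protein reports zero hits.
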