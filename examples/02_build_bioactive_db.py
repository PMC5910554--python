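"""Build a non-redundant bioactive-peptide database from two source tables.

Two pseudo-sources share the peptide FK under different activity labels;
merging unions activities and provenance into a single traceable entry.
"""

import tempfile
from pathlib import Path

from pepdig import SourceDescriptor, db_stats, ingest_source, merge_sources, save_db

tmp = Path(tempfile.mkdtemp())

(tmp / "milk.tsv").write_text(
    "sequence\tactivity\trecord_id\n"
    "FK\tACE-inhibitory\tm1\n"
    "IPP\tantihypertensive\tm2\n"
    "VPP\tantihypertensive\tm3\n"
)
(tmp / "egg.tsv").write_text(
    "sequence\tactivity\trecord_id\n"
    "FK\tantihypertensive\te1\n"
    "YAEERYPIL\tantioxidant\te2\n"
    "f1k\tbroken\te3\n"  # invalid sequence: goes to the skip report
)

ingests = [
    ingest_source(tmp / "milk.tsv", SourceDescriptor(db_name="MILK", format="tsv")),
    ingest_source(tmp / "egg.tsv", SourceDescriptor(db_name="EGG", format="tsv")),
]
for ing in ingests:
    print(f"{ing.db_name}: {len(ing.records)} records, {ing.n_skipped} skipped")

db = merge_sources(ingests)
entry = db.entries["FK"]
print(f"\nmerged entries: {len(db)}")
print(f"FK activities: {sorted(entry.activities)}")
print(f"FK sources:    {sorted(entry.sources)}")

stats = db_stats(db)
print(f"\nper-source counts (an entry may count toward several):\n{stats['per_source']}")
print(f"length groups:\n{stats['per_length']}")

save_db(db, tmp / "bioactive_db.tsv")
print(f"\nwrote {tmp / 'bioactive_db.tsv'}")
# 4 unique peptides; FK counts toward both MILK and EGG but is one entry.
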