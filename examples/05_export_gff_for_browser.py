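"""Export a protein-peptide alignment as GFF3 with enzyme tracks.

Each enzyme becomes a track (the GFF source column) and each miscleavage
level a subtrack (the miscleavage attribute); matched peptides carry
bioactivity/sources attributes for popup tooltips in a genome browser.
"""

import tempfile
from pathlib import Path

from pepdig import (
    ProteinRecord,
    build_match_index,
    digest_collection,
    features_for_protein,
    match_peptides,
    merge_sources,
    write_gff,
    write_track_hints,
)
from pepdig.bpdb import IngestResult

db = merge_sources(
    [IngestResult("DEMO", [("FK", "ACE-inhibitory", "r1"), ("LDK", "opioid", "r2")], [])]
)
protein = ProteinRecord("P1", "AFKALDKAGGRKP")
result = digest_collection([protein], ["trypsin", "thermolysin"], max_level=1)
matches = match_peptides(result.all_peptides(), build_match_index(db), "either")

fragments = [f for cell in result.cells() for f in result.fragments[cell]]
features = features_for_protein(protein, fragments, matches, which="all")

tmp = Path(tempfile.mkdtemp())
write_gff(features, tmp / "protein.gff3")
write_track_hints(features, tmp / "tracks.txt")

print((tmp / "protein.gff3").read_text())
print("track hints:")
print((tmp / "tracks.txt").read_text())
# Column 2 is the enzyme track; miscleavage=N in column 9 is the subtrack;
# bioactive peptides additionally carry bioactivity= and sources= attributes.
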