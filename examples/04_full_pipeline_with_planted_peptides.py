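"""Full pipeline on synthetic data with verified planted peptides.

Generates a 100-protein proteome and a fixture bioactive database, plants
50 database peptides so trypsin provably releases them (each insertion is
verified against the cleavage-site oracle), runs the complete job
(digest -> match -> reports -> GFF3), and checks recovery against the
plant manifest.
"""

import tempfile
from pathlib import Path

import pandas as pd

from pepdig import (
    JobConfig,
    load_builtin_rules,
    make_fixture_db,
    plant_peptides,
    random_proteome,
    releasable,
    run_job,
    save_db,
    write_fasta,
)

tmp = Path(tempfile.mkdtemp())
seed = 2024

proteome = random_proteome(100, length_mean=120, seed=seed)
db = make_fixture_db(seed=seed)
trypsin = load_builtin_rules().get("trypsin")
candidates = [s for s in db.sequences() if releasable(s, trypsin, max_level=1)][:50]
proteome, manifest = plant_peptides(proteome, candidates, "trypsin", max_level=1, seed=seed)
print(f"planted {len(manifest)} peptides into {len(proteome)} proteins")

write_fasta(proteome, tmp / "proteome.fasta")
save_db(db, tmp / "db.tsv")
job = run_job(
    JobConfig(
        input_fasta=str(tmp / "proteome.fasta"),
        db_path=str(tmp / "db.tsv"),
        out_dir=str(tmp / "out"),
        enzyme_ids=["trypsin"],
        max_level=1,
    )
)
print(f"job found {job['n_bioactive_peptides']} bioactive peptides; "
      f"outputs: {sorted(job['outputs'])}")

list_all = pd.read_csv(tmp / "out" / "list_all.csv")
origins = {}
for _, row in list_all.iterrows():
    origins.setdefault(row["peptide"], set()).update(row["origin_proteins"].split(","))
recovered = sum(
    1 for r in manifest.rows
    if r["peptide"] in origins and r["protein_id"] in origins[r["peptide"]]
)
print(f"recovered {recovered}/{len(manifest)} planted peptides with correct origins")

counts = pd.read_csv(tmp / "out" / "counts.csv")
print("\nper-level counts (peptides, bioactive, percentage):")
print(counts.to_string(index=False))
# Recovery is 100% by construction: every insertion was verified before use.
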