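"""Digest a single protein with trypsin at miscleavage levels 0 and 1.

Shows the cleavage sites the rule engine predicts, the level-0 fragments
(which partition the protein), and the level-1 products (each spanning one
uncut site).
"""

from pepdig import ProteinRecord, digest_protein, find_cleavage_sites, load_builtin_rules

ruleset = load_builtin_rules()
trypsin = ruleset.get("trypsin")

protein = ProteinRecord("demo", "MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGEENFKALVLIAFAQYLQQCPF")

sites = find_cleavage_sites(protein.sequence, trypsin)
print(f"protein length {len(protein)}, cleavage boundaries after residues: {sites}")

for level, frags in digest_protein(protein, trypsin, max_level=1).items():
    print(f"\nmiscleavage level {level}: {len(frags)} peptides")
    for f in frags:
        print(f"  {f.start:>3}-{f.end:<3} {f.sequence}")

# The level-0 peptides tile the protein end to end; each level-1 peptide is
# the concatenation of two consecutive level-0 peptides (one missed cut).
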