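# Methods

This note records the models, conventions and design choices behind
`pepdig`, in the order data flows through the pipeline.

## Cleavage-rule model

A protease is modelled as an ordered table of clauses over the
Schechter–Berger context window around a candidate boundary: positions
P4–P1 on the N-terminal side, P1′–P2′ on the C-terminal side, cleavage
between P1 and P1′. Each clause has a polarity (`cleave`/`block`), a small
positive priority, and a partial map from positions to allowed residue
sets. Among clauses whose constraints all hold at a boundary, the highest
priority decides; with no match the boundary is uncut. Three priority
levels suffice for the built-in enzymes: base specificity (1), exception
(2, e.g. the proline block for trypsin/chymotrypsin), and
exception-to-exception (3, e.g. trypsin's WK↓P and MR↓P cleavages and the
Keil block triplets).

Table validation rejects two same-priority clauses of opposite polarity
whose residue sets intersect at every position constrained by either
clause (with unconstrained positions counting as the full alphabet): that
is exactly the condition under which both could match one boundary, so
post-validation the decision is unambiguous and the engine can evaluate
clauses in descending priority and stop at the first match.

Two conservative conventions:

* **Out-of-window positions.** A clause constraining a position that falls
  outside the sequence does not match. Near-terminal boundaries therefore
  default toward "no cleavage" rather than acquiring phantom sites; for
  pepsin, whose clauses constrain P3 and P2′, this means the two
  N-terminal-most and the C-terminal-most boundaries can never cut,
  mirroring the lookaround semantics of the reference regexes.
* **Ambiguous residues.** Inputs may contain B, J, Z, X, U, O. A clause
  constraining a position that holds one never matches, so no cleavage
  decision is ever based on an ambiguous residue (fail-safe toward fewer,
  longer fragments).

The 15 built-in tables are transcribed from the ExPASy PeptideCutter
documentation: trypsin, chymotrypsin (high/low specificity), pepsin
(pH 1.3 and pH > 2), thermolysin, Lys-C, Lys-N, Arg-C, Asp-N, Glu-C,
proteinase K, clostripain, enterokinase and factor Xa. The test suite
cross-checks every enzyme against the independently transcribed
`pyteomics.parser.expasy_rules` regexes (trypsin against the base rule
minus the published exception set), and against a brute-force
per-boundary clause evaluator on random sequences. Rule tables are data,
not code: `register_rule` adds enzymes at run time (value semantics — the
original rule set is never mutated) and a nine-column TSV merges user
tables into the built-ins.

## Digestion and missed-cleavage semantics

Cutting at every predicted site yields the level-0 fragments, which
partition the protein (checked as an invariant: concatenation reproduces
the sequence; coordinates are gapless). A product with exactly *m* missed
cleavages spans *m* uncut internal sites, hence is a run of *m*+1
consecutive level-0 fragments; enumeration is a sliding window, giving the
count law |level-*m*| = max(0, *n*₀ − *m*) per protein. Levels are exact
and disjoint, never cumulative — the per-enzyme × per-level report grid
depends on this. The CLI bounds the level at 3 (the library accepts more
behind an explicit flag, for callers that need deeper windows).

Deduplication is global across the input collection, keyed by
(sequence, enzyme, level) — the same sequence found at two levels is two
records, since per-level counting would otherwise double-report — with all
(protein, start, end) occurrences kept in first-encounter order so origin
lists are deterministic. Fragments shorter than `min_len` (default 2) are
excluded before deduplication: the smallest catalogued bioactive peptides
are dipeptides, and single residues are not peptides in this context;
`min_len=1` restores them. Coordinates are 1-based inclusive everywhere,
matching GFF3, so no conversion happens at any module boundary.

Length classes follow the catalogue convention: very short (2–3), short
(4–29), long (≥ 30). Classification of a single residue is a domain error
rather than a fourth class.

## Bioactive database

Sources are heterogeneous (TSV with named columns, or FASTA with the
activity in the header); ingestion uppercases sequences, drops records
with non-amino-acid characters or length < 2 into a counted skip report,
and labels unannotated records `unannotated`. Merging produces one entry
per unique sequence with the set union of activities and of
(source, record id) pairs, so content is independent of source order
(checked against a set-based oracle) and every entry traces to all its
sources. Activity labels are kept verbatim — no ontology mapping — since
reconciliation beyond union would invent information. The persistent
format is a headered TSV with a version sentinel line; round-trip identity
is tested.

## Matching

At 100% identity, full coverage of the query (digested peptide) or the
subject (database entry) reduces alignment to substring containment, so
matching is exact string work: a hash probe for equality, and Aho-Corasick
automata for containment — one built over the database entries and scanned
with each peptide (entry inside peptide), one built over the peptide set
and scanned with each entry (peptide inside entry). Both directions are
single-pass; the automaton is implemented in-package in plain Python.
Relations are recorded as `equal`, `contains_subject` or
`contained_in_subject` with the offset of the covered region (0-based,
first occurrence when a pattern repeats). The default mode `either` takes
the union; `exact` is offered for conservative reporting, and the exact
hit set is a subset of every other mode by construction. The very-short /
short / long groups share identical matching semantics — the grouping is
an organizational device, not a semantic switch. Completeness and
soundness are tested against a quadratic all-pairs oracle.

Reports: "list all" has one row per matched (peptide, enzyme, level) with
origin proteins comma-joined in first-occurrence order and activities and
source databases ";"-joined lexicographically; "summary" has one row per
input protein (zero-hit proteins included) counting distinct matched
peptides with an occurrence in that protein; the counts grid reports
non-redundant peptide and bioactive counts with the percentage printed to
two decimals. All orderings are deterministic, so identical inputs give
byte-identical CSVs.

## GFF3 export

Each protein is a `polypeptide` feature spanning 1..L; each peptide
occurrence a `peptide` feature with source = enzyme id (the browser
track), a `miscleavage` attribute (the subtrack) and, for matched
peptides, `bioactivity` and `sources` attributes (the tooltip payload).
Strand and phase are inert constants ("+", ".") since peptides on proteins
have neither; reserved characters in attribute values are percent-encoded.
Files carry the version directive and per-protein `##sequence-region`
lines, and are checked in tests with a strict parser plus the invariant
that the subsequence at [start, end] reproduces every feature's Name.
Default scope exports matched peptides only (the discovery view);
`all` exports every fragment for digestion-design review. A plain-text
sidecar lists track → subtrack groupings; serving a browser is out of
scope.

## Synthetic data

`random_proteome` draws protein lengths from a clipped normal
(default mean 250, sd 75, minimum 2) and residues i.i.d. from a
composition model. The default composition boosts K and R to 5.5% each
(11% jointly, near their combined frequency in real proteomes) with the
remaining 18 residues uniform: a flat 5% alphabet makes tryptic fragments
unrealistically long. The generator emulates sequence composition only —
no domain structure, homology, or real length distribution — so passing
recovery tests demonstrates pipeline correctness, not performance on any
particular organism's proteome.

`plant_peptides` inserts each peptide with flanking context chosen so the
target enzyme cleaves at both ends: a left flank ending in a residue
context that cuts before the peptide's first residue, and a right flank
beginning with one that cuts after its last (found by searching 1–2
residue contexts against the rule engine, with an inert background
residue). Peptides with no possible right (left) context are placed at a
protein C-terminus (N-terminus), each terminus used at most once; a
peptide with neither becomes its own protein. Every insertion is then
*verified* against the cleavage-site oracle — the span must reproduce the
peptide, have boundaries or termini at both ends, and contain at most
`max_level` internal sites — and failed draws are re-drawn up to 100 times
per peptide, with exhaustion an error, never a silent skip. Insertions
keep a 5-residue margin from earlier plants; since no clause reaches
beyond 4 residues from a boundary, earlier plants stay valid (their
coordinates are shifted when an insertion lands upstream). The manifest
records final coordinates and the *observed* level, making 100% recovery
a construction-time guarantee and therefore a hard acceptance gate.

Peptides whose bare sequence contains more internal sites than the level
budget are rejected up front with an error naming the peptide.

`make_fixture_db` builds a deterministic database over ≥ 3 pseudo-sources
(default 80 very-short, 100 short, 25 long entries) with a configurable
number of sequences duplicated into a second source under a different
activity, exercising merge-union.

## Pipeline and determinism

`run_job` executes load → digest → match → report → GFF → manifest
synchronously. Any stage failure removes partial outputs and raises an
error naming the stage (the CLI maps it to a non-zero exit). The manifest
echoes the effective configuration and SHA-256 hashes of all result
files; timings go only to the log, so every result file is byte-stable
across runs. Defaults encode the canonical job: trypsin, no miscleavage,
`either` matching, `min_len` 2.

## Problem sizes and performance

The default test suite digests hundreds of random proteins per property
and runs the scaled (300-protein, 15-enzyme, levels 0–3) job; the
acceptance script runs the full 3,000-protein (~750k residue) equivalent,
which completes in roughly a minute on one CPU with peak memory around
3 GB — comfortably inside the sub-20-minute envelope the tool targets for
proteome-scale jobs. Matching cost is linear in total peptide length plus
hits.

## Known limitations

* Cleavage rules are deterministic specificity tables; no probabilistic
  cleavage, chemical cleavers, or kinetics. Missed cleavages are
  enumerated combinatorially, not modelled causally.
* The enzyme tables follow PeptideCutter's published specificities;
  laboratory preparations differ (e.g. semi-specific activity).
* Matching is exact substring containment — no partial-coverage or
  similarity matching, and no bioactivity prediction for unmatched
  peptides (that is a different tool category).
* Double/sequential digestion is not simulated; per-enzyme results are
  reported side by side so users can design combined digests themselves.
* The bioactive fixture database is synthetic; real source databases are
  ingested via the descriptor mechanism but not scraped or redistributed.
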