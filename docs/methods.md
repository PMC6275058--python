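# Methods

## The nomenclature rule and how identity is measured

P450 naming groups sequences by global amino-acid identity: strictly more
than 40% identity to a named P450 places a query in that P450's family,
strictly more than 55% in its subfamily. Identity exactly at a cut-off
falls to the lower tier. The convention's sources do not pin down the
alignment recipe or the identity denominator, so `cypcensus` declares one
and applies it uniformly:

- **Alignment**: Needleman–Wunsch global alignment with affine gaps
  (Gotoh three-state DP), BLOSUM62, gap open 10, gap extend 0.5
  (EMBOSS-needle-style defaults, the most widely reproduced). A gap of
  length *k* costs `open + (k-1)·extend`; end gaps are penalized (true
  global alignment).
- **Identity** = `100 × identical aligned residue pairs / total alignment
  columns`, gaps included — the strictest and symmetric denominator.
- **Determinism**: score-optimal global alignments are generally not
  unique, and co-optima can disagree on identity. The aligner therefore
  optimizes the lexicographic tuple *(score, identical columns,
  −alignment length)*; the reported identity is a pure function of the
  two sequences. Scores are kept in exact doubled-integer arithmetic so
  no floating-point comparison enters the DP.
- **Best hit**: the reference with maximal identity, ties broken by
  lexicographically smallest CYP name.

Correctness is checked two independent ways: (1) an exhaustive oracle
that enumerates every possible set of aligned residue pairs (match
chains) with the closed-form minimal affine gap cost per chain, compared
on all 1,860,496 sequence pairs of length ≤ 5 over a 4-letter alphabet;
(2) Biopython's `PairwiseAligner` configured identically, compared on
random long pairs (score only, since Biopython's co-optimal tie-break is
unspecified).

Novel calls get deterministic placeholder labels: a new subfamily takes
the next unused letter in its family (A..Z, then AA..); a new family
takes `CYPNOVEL<n>` in assignment order (official numbers require the
nomenclature committee). Member numbers continue after the largest member
in the reference library for that (family, subfamily).

## Detection

The desk-scale detector requires (a) length ≥ 250 aa (bacterial P450s run
~400 aa; 250 excludes fragments without excluding divergent P450s) and
(b) a match to the heme-ligand signature
`[FW][SGNH]x[GD]x[RKHPT]C[LIVMFAP][GAD]` — the conserved region around
the axial cysteine that ligates the heme iron. The K-helix `ExxR` motif
is recorded as a confidence annotation but not required by default. `X`
residues never satisfy a motif position (conservative). Real analyses
that used a domain-search service can import its hit table instead
(`import_external_hits`), which takes precedence over the motif scan.

## Census statistics

- **Diversity percentage** = `100 × number of P450 families / total
  P450s`, rounded half-up to one decimal. Note: applying this formula to
  the published genus-wide inputs (13 families, 507 P450s) yields 2.6,
  while the source literature prints 3.9% for that comparison (and 72%
  for mycobacteria, likewise inconsistent with 77 families over ~2100
  P450s); the denominator actually used there is not recoverable from the
  text. The formula is implemented as stated and the discrepancy is
  surfaced, not corrected.
- **Presence/absence heatmap**: families × species matrix encoded −3 for
  presence and 3 for absence; hierarchical clustering on both axes with
  Euclidean distance on the encoded values exactly (not 0/1 — the
  orderings coincide, but the export is faithful to the encoding), with
  average linkage (UPGMA) by default (`single`/`complete` available).
  Leaf order is deterministic; single-row/column axes keep identity
  order. Exports: matrix TSV, axis orders, newick dendrograms.
- **Species with zero P450s are retained** — they are real census rows
  and all-absent heatmap columns.
- **Validator**: `validate_census` checks a reported per-species count
  distribution against reported totals (Σ count×species = total P450s,
  Σ species = P450-bearing species) and optionally against a computed
  census. It reports discrepancies and never throws; fed the published
  *Bacillus* distribution it flags that the printed bins sum to 525 P450s
  over 116 species against printed totals of 507 and 114 — the package
  surfaces such conflicts rather than silently correcting any number.
- All printed percentages use half-up rounding: one decimal in detail
  tables, nearest integer for headline figures (e.g. "61%", "22%").

## BGC cross-referencing

Cluster tables carry the shape of anti-SMASH region output (species,
replicon, cluster number, hyphen-joined type string, interval); cluster
prediction itself is out of scope. Coordinates are 1-based inclusive
throughout. Membership policy:

- `any_overlap` (default, `min_fraction` 0): ≥1 bp overlap counts —
  predicted cluster regions include boundary-spanning genes, so inclusion
  by overlap best mimics consumed output.
- `full_containment`: the gene interval must lie inside the cluster.

A gene overlapping two clusters yields two association records (published
association tables list such duplicates as separate rows), so totals
count gene-cluster pairs; the summary also reports distinct genes. Type
strings are opaque tokens compared case-insensitively after trimming.
The replicon-kind stratification (chromosome vs plasmid) uses exact type
strings for shared/unique set comparisons.

## Synthetic data: what it emulates and what it does not

The generator emulates the *shape* of a genus census: a reference library
(one random 400-aa base per family, heme and ExxR motifs planted at fixed
offsets, family bases verified ≤30% mutual identity and redrawn on
violation; subfamily variants are 50%-identity mutants of the base),
proteomes with planted P450s derived from references at controlled
identity levels, motif-free decoys, gene coordinates on one or two
replicons (second replicon a plasmid with probability 0.45, matching the
roughly half of census genomes that carry plasmids), and non-overlapping
10–80 kb cluster intervals (an overlapping mode exercises the
multiplicity rule). Defaults follow the stated study conditions: identity
levels {70, 50, 25}% (each ≥10 points from both thresholds), 10 species ×
3 P450s, half the planted genes inside clusters, exactly
`round(fraction × total)` chosen by a seeded permutation. All outputs are
pure functions of (parameters, seed).

Mutation is substitution-only: exactly `round((1−target)·L)` unlocked
positions change to a different residue, so the *ungapped* identity is
`(L−k)/L` exactly. One measured caveat: below ~50% identity the optimal
*global* alignment of such a mutant may include gaps and recover extra
matches, so the realized identity can drift off target by a couple of
points (e.g. a 40% construction realizing 39.9%). Recovery experiments
are unaffected (levels sit ≥10 points from the thresholds), but
threshold-boundary experiments need the measured identity to be exact, so
`mutate_to_exact_identity` draws deterministic variants from seed
sub-streams until the aligner reports the target exactly (~1 in 8 draws
at 40%), and tests verify the realized identity before asserting the
classification tier.

What the generator does **not** emulate: phylogenetic sequence evolution
(mutations are i.i.d. uniform, no rate heterogeneity or indels by
default), codon-level genome structure (gene length is 3× protein
length; no operons or strand bias), and realistic cluster/gene density.
Passing recovery tests therefore demonstrates the pipeline's logic —
detection, threshold arithmetic, bookkeeping, interval algebra — not
annotation accuracy on real divergent proteomes, where detection
sensitivity depends on motif conservation and identity to references is
not controlled.

## Problem sizes and numerical choices

The packaged published association table (112 rows) is aggregated
exactly. Synthetic experiments default to a 5-family library with 50
queries per identity level and a 10-species genus (30 planted P450s, 50
decoys); these sizes give exact recovery targets while keeping any run in
seconds. The alignment oracle comparison covers every 4-letter pair to
length 5. Degenerate inputs are defined, not special-cased: empty
candidate lists classify to empty output, an empty association list
summarizes to zeros, an empty census has undefined diversity (error on
access), and single-leaf clustering axes return identity order.

## Known limitations

- The alignment recipe is a declared convention; censuses computed with
  other tools (BLAST identities, local alignments, different gap costs)
  will differ near the thresholds.
- The motif detector trades sensitivity for simplicity; divergent P450s
  with non-canonical heme signatures require the external-hits path.
- Novel-family placeholders are run-scoped: two runs (or two species in
  one run classified separately) may both allocate `CYPNOVEL1` for
  unrelated proteins.
- The full published genus-wide census (128 genomes, 507 P450s, 1098+26
  BGCs) requires external proteome downloads and cluster-prediction
  services and is not reproduced here; the packaged association table and
  synthetic genera are the supported evidence surface.
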