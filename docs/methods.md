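# Methods

## Problem and model

A NUMT is a fragment of mitochondrial DNA fixed in a nuclear chromosome.
After insertion it evolves as a pseudogene: substitutions accumulate roughly
uniformly, short indels appear, and old insertions decay toward background.
Given an assembly and the species' mitochondrial *cox1* gene, the package
finds local alignments of the gene against the scaffolds, removes alignments
that are unlikely to be genuine nuclear insertions, merges the survivors into
insertion sites, and places the extracted site sequences on a distance tree.

All internal coordinates are 0-based half-open on the forward strand of the
named sequence; 1-based inclusive conventions (BLAST tabular, display labels)
are converted only at format boundaries in `numtscan.io`. This removes the
usual off-by-one error class at the cost of one conversion layer.

## Homology search

The scanner is a standard seed-and-extend local aligner:

* **Seeds** — exact k-mer matches (default k = 11, the classical blastn word
  size) between scaffold and query, indexed separately for the forward and
  reverse-complement query strands. k-mers containing N are skipped and N
  never counts as a match: ambiguity should not manufacture homology.
* **Extension** — gapped x-drop dynamic programming (Gotoh three-state
  H/E/F recurrence) leftward and rightward from the seed anchor, pruning
  cells whose running score falls more than `x_drop` (default 50) below the
  best seen. The alignment ends at the best-scoring cell, so hits may
  overrun a planted fragment by the few columns of chance flank matches that
  keep the score rising.
* **Scoring** — match +2, mismatch −3, a gap of length L costs
  `gap_open + L*gap_extend` = 5 + 2L. These mirror blastn defaults. The
  score floor (`score_min` = 60, a perfect 30-bp match) sits far below the
  100-nt length filter, so the *filter*, not the aligner, governs the length
  cutoff.
* **Redundancy control** — a seed lying entirely on the match path of an
  already-extended alignment is skipped; afterwards, overlapping hits on the
  same scaffold and strand are collapsed to the best-scoring one (ties:
  longer subject span, then leftmost). BLAST HSP lists contain shadow hits
  that would otherwise inflate site counts.

No E-value is computed: Karlin–Altschul calibration is out of scope, the
score floor plays its role at desk scale, and runs meant to mirror a real
blastn invocation should use the `--blast-tab` ingestion path, which accepts
any 12-column `-outfmt 6` file (E-values are carried as metadata only, never
filtered on).

`smith_waterman` is the exact counterpart (full Gotoh matrices, anti-diagonal
vectorisation, guarded to 10^7 cells). Ties among optimal end cells are broken
by longest alignment, then leftmost start; within the traceback the
preference is diagonal > vertical > horizontal. It is used three ways: as the
verification oracle for the heuristic search, to realign trace-less BLAST
hits before MSA induction, and in tests it is itself cross-checked against
Biopython's `PairwiseAligner`.

## Exclusion filters

Applied per hit, in order, with every firing criterion recorded:

| criterion | rule (defaults) | rationale |
|---|---|---|
| `min_length` | alignment columns < 100 (strict) | short hits are conserved-motif noise |
| `scaffold_span` | subject span / scaffold length ≥ 0.95 | a scaffold that *is* the alignment is mitochondrial contamination in the assembly, not an insertion |
| `edge` | hit start ≤ 10 bp from scaffold start, or end within 10 bp of scaffold end | edge alignments are truncated and cannot be distinguished from assembly artifacts |

Two boundary readings were open and are fixed as follows: a span of exactly
95 % is **removed** (the criterion targets mito-derived scaffolds, so the
boundary belongs with removal), and the span numerator is the subject
interval length (`se − ss`), not the alignment column count, because the
criterion is a statement about scaffold coverage. The edge tolerance default
of 10 bp (configurable; 0 = strict abutment) reflects that polished
assemblies rarely place an alignment at exact base 0.

Surviving hits on one scaffold merge transitively when their interval gap is
≤ `merge_gap` (default 1000 bp), regardless of strand: one insertion event
fragments into nearby HSPs through indel-rich or low-identity stretches, and
inverted duplications within one site would otherwise double-count. The
merged locus — not the HSP — is the countable insertion site. `merge_gap` and
`edge_tol` are the two parameters with no externally fixed value, so
`analysis/03_evaluate.py` sweeps both; on the synthetic truth the site count
is flat across merge_gap 0–5000 and edge_tol 0–200. Real replication studies
should repeat that sweep.

## Synthetic genomes

`numtscan.simulate` plants mutated copies of the query into i.i.d. background
scaffolds (default GC 0.40; the query generator defaults to GC 0.38 and
1534 bp, typical of an AT-rich invertebrate mitochondrial *cox1*). Decay is
modelled as uniform substitution at a per-site rate plus indels of length
1–3 (geometric, rate per site). The substitution model is deliberately the
Jukes–Cantor process assumed by the distance correction downstream, so
divergence parameters are recoverable in a closed loop. Placement classes map
one-to-one onto filter branches: `interior` (detectable when the planted
copy is ≥ 100 nt), `edge_start`/`edge_end` (abutting a scaffold end),
`contamination` (a dedicated scaffold ~97 % covered by the plant). Plants
never overlap, and `expected_detectable` is precomputed from the same
thresholds the detector uses, so recall is measured only over plants the
filters are meant to keep — separating filter semantics from aligner
sensitivity. A fixed seed yields byte-identical FASTA and truth tables.

What the simulator does **not** model: transposable-element background,
assembly gaps and errors, GC heterogeneity, empirical mitochondrial mutation
spectra, and very old (saturated) insertions. Passing benchmarks therefore
demonstrate the pipeline's internal correctness and its behaviour at the
simulated divergences (≤ 0.20), not sensitivity to ancient NUMTs in repeat-
rich real genomes — a conservative search misses highly decayed copies by
construction.

## Phylogeny

The MSA is *reference-anchored* rather than inferred: each NUMT's pairwise
alignment to the query is projected into query coordinates (match/mismatch
columns copy the scaffold residue; deletions leave gaps; insertions relative
to the query are dropped). This is deterministic, lets hits from different
scaffolds or species share one coordinate system, and avoids an external
aligner dependency; the cost is that NUMT-specific insertions carry no
signal. The extracted NUMT FASTA is always exported so MAFFT + IQ-TREE can
be run externally when a model-based tree is wanted; at the simulated
divergences the monophyly conclusion is method-robust.

Distances are JC69, d = −(3/4)·ln(1 − (4/3)·p), with p the mismatch fraction
over sites where both rows are resolved (non-gap, non-N). Pairs sharing fewer
than `min_shared_sites` sites (default 100, matching the length filter —
distances on fewer sites are noise-dominated) or with p ≥ 0.75 (beyond JC
identifiability) are flagged and excluded; tree building greedily drops the
label with the most flagged pairs until the matrix is complete, and raises
if fewer than two labels survive.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q criterion,
ties broken by sorted label pair (the Q minimum is evaluated on the upper
triangle only, since floating-point summation order makes Q asymmetric in
the last bit). Negative branch lengths are clamped to zero with the total
deficit recorded on the tree. NJ recovers additive matrices exactly, which
the benchmarks exploit. Monophyly of a label set on the unrooted tree means
the set (or its complement) equals one side of some edge-induced
bipartition; singletons are trivially monophyletic.

## Verification experiments (benchmarks)

Problem sizes were chosen so the whole suite runs in minutes on one CPU:

* **Filter boundary fixture** — six constructed hits at the exact boundaries
  (99/100 columns; 94 %/95 % span; interior/edge): the ledger is forced.
* **Oracle equivalence** — 200 instances: a 100–400 nt fragment at ≤ 10 %
  divergence planted in a ≤ 2 kb scaffold (resampled until an exact 11-mer is
  shared); the search's best score must equal the Smith–Waterman optimum over
  both strands.
* **Planted recovery** — 50 interior plants (150–800 nt, divergence uniform
  0–0.20, indel rate 0.01) across ~5 Mb in 55 scaffolds, plus edge and
  contamination distractors; precision and recall at 50 % reciprocal overlap.
* **Branch coverage** — 20 seeded configs with one plant per class; every
  contamination plant must fall to `scaffold_span`, every edge plant to
  `edge`, every sub-threshold plant to `min_length`. Sub-threshold plants are
  40–85 nt so that alignment end wobble cannot straddle the 100-column
  boundary — the boundary itself is what the constructed fixture probes.
* **NJ recovery** — 100 random additive matrices from random binary trees
  (5–12 taxa, branch lengths U(0.05, 1)); exact topology recovery, and
  3-taxon pendant lengths against the closed form a = (d_AB + d_AC − d_BC)/2.
* **Monophyly** — 3 species × 5 NUMTs from one 800-bp query, ancestor copies
  at divergence 0.15, within-species copies at 0.02, 40 replicates; fraction
  of trees in which every species is monophyletic.

Evaluation matches predictions to truth at 50 % reciprocal overlap — the
standard interval-benchmark convention, insensitive to ragged alignment ends.
Recall is over expected-detectable plants only; precision is reported as null
when there are no predictions.

## Numerical and degenerate-input choices

* Gap cost of a length-L gap is `open + L·extend` (first gap column costs
  open + extend), matching the scoring arithmetic above.
* x-drop pruning is applied to H only (the standard heuristic); a fully dead
  row terminates extension.
* `smith_waterman` enumerates at most 64 tied optimal end cells before
  applying the tie-break, and raises on inputs beyond the 10^7-cell guard.
* FASTA input is sanitized (uppercase, U→T, anything outside ACGTN → N);
  records under 80 % IUPAC nucleotide characters are rejected as probable
  protein.
* Zero hits is a successful scan (exit 0, empty BED); the tree step is
  skipped below two loci or when no pair shares enough sites.
* Two-taxon "trees" are a single edge carrying the full distance; Newick
  labels have reserved characters replaced by `_`.

## Limitations

The detector is validated on simulation only; the full-scale counts on
deposited assemblies depend on the unstated details of the original BLAST
parameterisation and on the merge/edge conventions, which is why both are
exposed as flags and swept in the analysis. The search is nucleotide-space
only (no protein-space search, no spliced alignment), single-query, and
reports no E-values. The tree is distance-based without support values;
saturated pairs are excluded rather than modelled.
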