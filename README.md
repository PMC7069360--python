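# numtscan

Detection of **NUMTs** — nuclear copies of mitochondrial DNA — in genome
assemblies, using the mitochondrial *cox1* gene (the standard animal
DNA-barcoding marker) as the homology query. NUMTs are *cox1* pseudogenes
that decay in the nucleus; because they co-amplify with the genuine
mitochondrial marker, they are a persistent threat to barcoding and
metabarcoding studies, and counting the insertion sites per genome is the
first step in assessing that risk for a taxon. The package was built for
screening large invertebrate (decapod crustacean) assemblies but is
query-agnostic.

## What it does

1. **Homology search** (`numtscan.search`) — a self-contained blastn-style
   seed-and-extend scanner: exact 11-mer seeds on both strands, gapped x-drop
   extension under affine gap costs (match +2, mismatch −3, gap of length
   *L* costs 5 + 2*L*), score floor 60. A full Smith–Waterman (Gotoh
   three-matrix) implementation serves as the exact oracle for the heuristic,
   and precomputed BLAST hits (12-column `-outfmt 6`) can be ingested instead
   of the built-in search for exact parity with a real blastn run.
2. **Exclusion filters** (`numtscan.call`) — a hit is removed if
   (a) its alignment is shorter than 100 nt, (b) it spans ≥ 95 % of its
   scaffold (the signature of a mitochondrial contamination scaffold rather
   than a nuclear insertion), or (c) it lies at a scaffold edge (within
   10 bp by default), where truncated alignments are uninterpretable. All
   firing criteria are recorded per hit.
3. **Insertion sites** — surviving hits on one scaffold are merged
   transitively (gap ≤ 1 kb, strand-agnostic) into loci, the countable unit;
   locus sequences are extracted in query orientation.
4. **Phylogeny** (`numtscan.phylo`) — a deterministic reference-anchored MSA
   in query coordinates, Jukes–Cantor distances
   d = −(3/4)·ln(1 − (4/3)·p) over jointly resolved sites, a Saitou–Nei
   neighbor-joining tree, and per-species monophyly tests on the unrooted
   tree's bipartitions. The extracted NUMT FASTA is also written so external
   tools (MAFFT, IQ-TREE) can be run for replication.
5. **Simulator** (`numtscan.simulate`) — synthetic assemblies with planted,
   ground-truthed NUMTs covering every filter branch (interior, edge,
   contamination, sub-threshold), so precision and recall are measurable
   without any download.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale and
write their tables under `results/`:

```sh
python analysis/01_simulate.py   # plant NUMTs in a synthetic assembly
python analysis/02_scan.py      # detect insertion sites
python analysis/03_evaluate.py  # score against truth; parameter sweep
python analysis/04_tree.py      # multi-species NUMT tree + monophyly
```

`01_simulate.py` builds a 13-scaffold, ~0.4 Mb assembly with 14 planted
*cox1* copies and prints:

```
assembly: 13 scaffolds, 401,124 bp
planted insertions: 14 (10 expected detectable)
  interior: 11
  edge_start: 1
  edge_end: 1
  contamination: 1
```

Eleven interior plants are made, but one is 40–85 nt long — below the 100-nt
filter — so 10 are expected detectable. `02_scan.py` then reports (abridged):

```
"n_hits_input": 15, "n_hits_kept": 10,
"removed_by_reason": {"edge": 3, "min_length": 1, "scaffold_span": 1},
"insertion_sites": 10
outfmt-6 ingestion reproduces the summary: True
```

Exactly the ten detectable plants survive: the contamination scaffold falls
to the span criterion (it also abuts the edge, so both reasons are logged),
the two edge plants to the edge criterion, and the sub-threshold plant to the
length criterion. `03_evaluate.py` scores the calls at 50 % reciprocal
overlap — precision 1.0, recall 1.0 — and sweeps the two free parameters
(`merge_gap` 0–5000, `edge_tol` 0–200): the site count stays 10 across the
whole grid, i.e. the counts sit on a wide plateau around the defaults.
`04_tree.py` simulates NUMT sets from three species (substitution divergence
0.15 between species, 0.02 within), builds the JC + NJ tree and reports

```
per-species monophyly: {'sp1': True, 'sp2': True, 'sp3': True}
monophyly recovered in 40/40 replicates
```

The same pipeline is exposed as a CLI for real assemblies:

```sh
numtscan scan --genome assembly.fa --query cox1.fa --out run/ \
    [--blast-tab hits.outfmt6.tsv] [--min-len 100] [--max-span-frac 0.95] \
    [--edge-tol 10] [--merge-gap 1000]
numtscan simulate|tree|evaluate --help
```

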