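"""Desk-scale study conditions for validating the detector and the phylogeny.

Each function sets up one verification experiment at the sizes used throughout
the project's analyses, runs the pipeline on it, and returns measured
quantities:

* a constructed boundary fixture for the three exclusion filters,
* seed-and-extend vs. exact Smith-Waterman score agreement on planted
  instances,
* recovery (precision/recall) of NUMTs planted across a ~5 Mb assembly,
* per-filter-branch removal of the plant class each criterion targets,
* neighbor-joining topology recovery on random additive matrices, and
* per-species monophyly recovery on multi-species NUMT simulations.

All randomness flows from one integer seed through ``numpy.random.SeedSequence``
spawns, so every experiment is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .call import FilterParams, count_sites, filter_hits, merge_insertion_sites
from .io import AlignmentHit, BedRecord, GenomeAssembly, reverse_complement
from .phylo import (UnrootedTree, jc_distance, msa_from_equal_length_sequences,
                    neighbor_joining, nj_tree, species_monophyly)
from .pipeline import evaluate_predictions
from .search import SearchParams, search, smith_waterman
from .simulate import (InsertionSpec, SimConfig, generate_background,
                       mutate_fragment, plant_multispecies, plant_numts,
                       random_query)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# 1. filter boundary fixture


def filter_boundary_fixture() -> tuple[GenomeAssembly, list[AlignmentHit], dict]:
    """Six constructed hits probing each criterion's boundary on a 10 kb and a
    1 kb scaffold, with the keep/remove/reason ledger they must produce."""
    assembly = GenomeAssembly({
        "big": "A" * 10_000,
        "small": "A" * 1_000,
    })

    def hit(sid, ss, se, aln_len):
        return AlignmentHit(
            query_id="q", scaffold_id=sid, q_start=0, q_end=min(aln_len, 1534),
            s_start=ss, s_end=se, strand="+", aln_len=aln_len,
            identity=1.0, score=float(2 * aln_len),
        )

    hits = [
        hit("big", 2000, 2099, 99),     # below length floor
        hit("big", 2000, 2100, 100),    # at the floor: kept
        hit("small", 0, 950, 950),      # spans 95% AND starts at the edge
        hit("small", 20, 960, 940),     # 94% span, interior: kept
        hit("big", 0, 300, 300),        # at the scaffold start
        hit("big", 9700, 10_000, 300),  # at the scaffold end
    ]
    expected = {
        0: ("removed", {"min_length"}),
        1: ("kept", set()),
        2: ("removed", {"scaffold_span", "edge"}),
        3: ("kept", set()),
        4: ("removed", {"edge"}),
        5: ("removed", {"edge"}),
    }
    return assembly, hits, expected


def run_filter_fixture() -> dict:
    assembly, hits, expected = filter_boundary_fixture()
    report = filter_hits(hits, assembly, FilterParams())
    correct = 0
    for idx, record in enumerate(report.records):
        want_state, want_reasons = expected[idx]
        ok = (record.kept == (want_state == "kept")) and set(record.reasons) == want_reasons
        correct += ok
    return {"n_hits": len(hits), "correct_decisions": correct}


# ---------------------------------------------------------------------------
# 2. oracle equivalence


def oracle_equivalence_instance(rng: np.random.Generator):
    """One planted instance (scaffold <= 2 kb) guaranteed to share an exact
    11-mer with the query on the planted strand."""
    while True:
        qlen = int(rng.integers(300, 601))
        query = random_query(qlen, rng=rng, name="q")
        flen = int(rng.integers(100, min(400, qlen) + 1))
        qs = int(rng.integers(0, qlen - flen + 1))
        divergence = float(rng.uniform(0, 0.10))
        frag, _, _ = mutate_fragment(query.sequence[qs:qs + flen], divergence, 0.005, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = frag if strand == "+" else reverse_complement(frag)
        slen = int(rng.integers(max(500, len(placed)), 2001))
        pos = int(rng.integers(0, slen - len(placed) + 1))
        bg = generate_background(slen, 0.4, rng)
        scaffold = bg[:pos] + placed + bg[pos:]
        oriented = query.sequence if strand == "+" else reverse_complement(query.sequence)
        kmers = {oriented[i:i + 11] for i in range(len(oriented) - 10)}
        if any(scaffold[i:i + 11] in kmers for i in range(len(scaffold) - 10)):
            return query, scaffold


def run_oracle_equivalence(seed: int, n_instances: int = 200) -> dict:
    """Over planted random instances, compare the best seed-and-extend score
    with the optimal Smith-Waterman score over both strands."""
    rng = _rng(seed, 2)
    agree = 0
    for _ in range(n_instances):
        query, scaffold = oracle_equivalence_instance(rng)
        assembly = GenomeAssembly({"s": scaffold})
        hits = search(query, assembly, SearchParams())
        best = max((h.score for h in hits), default=0.0)
        sw = max(
            smith_waterman(query.sequence, scaffold).score,
            smith_waterman(reverse_complement(query.sequence), scaffold).score,
        )
        agree += best == sw
    return {"n_instances": n_instances, "n_agree": agree,
            "agreement_rate": agree / n_instances}


# ---------------------------------------------------------------------------
# 3. planted recovery at ~5 Mb


def planted_recovery_conditions(rng: np.random.Generator) -> tuple[SimConfig, "QueryGene"]:
    query = random_query(1534, rng=rng)
    insertions = [
        InsertionSpec("interior", (150, 800), float(rng.uniform(0, 0.20)), 0.01)
        for _ in range(50)
    ]
    insertions += [
        InsertionSpec("edge_start", (150, 500), 0.02, 0.0),
        InsertionSpec("edge_end", (150, 500), 0.02, 0.0),
        InsertionSpec("contamination", (400, 800), 0.02, 0.0),
    ]
    config = SimConfig(
        n_scaffolds=55, scaffold_length_range=(80_000, 100_000),
        gc=0.40, insertions=insertions,
    )
    return config, query


def run_planted_recovery(seed: int) -> dict:
    """Plant 50 interior NUMTs (>=150 nt, divergence <= 0.20) across ~5 Mb,
    run the full detector, and score at 50% reciprocal overlap."""
    rng = _rng(seed, 3)
    config, query = planted_recovery_conditions(rng)
    assembly, truths = plant_numts(config, query, rng)
    params = FilterParams()
    hits = search(query, assembly, SearchParams())
    report = filter_hits(hits, assembly, params)
    loci = merge_insertion_sites(report.kept_hits, params)
    predictions = [
        BedRecord(l.scaffold_id, l.start, l.end, l.label,
                  round(100 * l.best_identity), l.strand)
        for l in loci
    ]
    scores = evaluate_predictions(predictions, truths)
    scores["insertion_sites"] = count_sites(loci)["total"]
    scores["genome_bp"] = assembly.total_length
    return scores


# ---------------------------------------------------------------------------
# 4. filter-branch coverage


def run_filter_branch_coverage(seed: int, n_configs: int = 20) -> dict:
    """Across seeded configs, check that hits over every contamination plant
    are removed by scaffold_span, every edge plant by edge, and every
    sub-100-nt plant by min_length."""
    params = FilterParams()
    checked = {"contamination": 0, "edge": 0, "short": 0}
    correct = {"contamination": 0, "edge": 0, "short": 0}
    for c in range(n_configs):
        rng = _rng(seed, 100 + c)
        query = random_query(1000, rng=rng)
        insertions = [
            InsertionSpec("interior", (150, 500), 0.05, 0.0),
            InsertionSpec("edge_start", (150, 400), 0.02, 0.0),
            InsertionSpec("edge_end", (150, 400), 0.02, 0.0),
            InsertionSpec("contamination", (300, 600), 0.02, 0.0),
            # clearly sub-threshold: end wobble of a few chance flank matches
            # must not straddle the 100-column boundary (the boundary itself
            # is probed by the constructed filter fixture)
            InsertionSpec("interior", (40, 85), 0.0, 0.0),
        ]
        config = SimConfig(
            n_scaffolds=5, scaffold_length_range=(15_000, 30_000),
            gc=0.40, insertions=insertions,
        )
        assembly, truths = plant_numts(config, query, rng)
        hits = search(query, assembly, SearchParams())
        report = filter_hits(hits, assembly, params)

        def overlapping_records(truth):
            return [
                r for r in report.records
                if r.hit.scaffold_id == truth.scaffold_id
                and r.hit.s_start < truth.end and truth.start < r.hit.s_end
            ]

        for truth in truths:
            recs = overlapping_records(truth)
            if truth.placement_class == "contamination":
                checked["contamination"] += 1
                correct["contamination"] += bool(recs) and all(
                    not r.kept and "scaffold_span" in r.reasons for r in recs
                )
            elif truth.placement_class in ("edge_start", "edge_end"):
                checked["edge"] += 1
                correct["edge"] += bool(recs) and all(
                    not r.kept and "edge" in r.reasons for r in recs
                )
            elif truth.end - truth.start < params.min_len:
                checked["short"] += 1
                correct["short"] += bool(recs) and all(
                    not r.kept and "min_length" in r.reasons for r in recs
                )
    total = sum(checked.values())
    good = sum(correct.values())
    return {"checked": checked, "correct": correct,
            "n_plants": total, "n_correct": good,
            "removal_rate": good / total if total else None}


# ---------------------------------------------------------------------------
# 5. NJ on random additive matrices


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree (leaf attachment to a random edge) with
    branch lengths U(0.05, 1); returns (adjacency, labels, leaf node ids)."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}, 2: {}, 3: {}}
    next_id = 4
    center = 3
    for leaf in (0, 1, 2):
        w = float(rng.uniform(0.05, 1.0))
        adj[center][leaf] = w
        adj[leaf] = {center: w}
    leaf_ids = [0, 1, 2]
    for _ in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = adj[u][v]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = next_id
        next_id += 1
        new_leaf = next_id
        next_id += 1
        del adj[u][v]
        del adj[v][u]
        adj[mid] = {u: split, v: w - split, new_leaf: float(rng.uniform(0.05, 1.0))}
        adj[u][mid] = split
        adj[v][mid] = w - split
        adj[new_leaf] = {mid: adj[mid][new_leaf]}
        leaf_ids.append(new_leaf)
    return adj, labels, leaf_ids


def _tree_distances(adj, leaf_ids) -> np.ndarray:
    n = len(leaf_ids)
    D = np.zeros((n, n))
    for i, src in enumerate(leaf_ids):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for j, dst in enumerate(leaf_ids):
            D[i, j] = dist[dst]
    return D


def _true_bipartitions(adj, labels, leaf_ids) -> set[frozenset[str]]:
    label_of = {node: labels[i] for i, node in enumerate(leaf_ids)}
    leafset = frozenset(labels)
    anchor = min(labels)
    parts: set[frozenset[str]] = set()
    for u in adj:
        for v in adj[u]:
            if u >= v:
                continue
            side = set()
            seen = {u, v}
            stack = [v]
            while stack:
                node = stack.pop()
                if node in label_of:
                    side.add(label_of[node])
                for nbr in adj[node]:
                    if nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
            fside = frozenset(side)
            if anchor in fside:
                fside = frozenset(leafset - fside)
            if 1 < len(fside) < len(labels) - 1:
                parts.add(fside)
    return parts


def run_nj_additive_recovery(seed: int, n_matrices: int = 100) -> dict:
    """Exact topology recovery of NJ on random additive matrices (5-12 taxa),
    plus the worst 3-taxon pendant-length error against the closed form."""
    rng = _rng(seed, 5)
    recovered = 0
    for _ in range(n_matrices):
        n_taxa = int(rng.integers(5, 13))
        adj, labels, leaf_ids = random_additive_tree(n_taxa, rng)
        D = _tree_distances(adj, leaf_ids)
        tree = neighbor_joining(D, labels)
        mine = {s for s in tree.bipartitions() if 1 < len(s) < n_taxa - 1}
        truth = _true_bipartitions(adj, labels, leaf_ids)
        recovered += mine == truth

    # 3-taxon closed form: a = (dAB + dAC - dBC)/2, etc.
    dab, dac, dbc = 2.0, 3.0, 3.0
    tri = neighbor_joining(
        np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]]), ["A", "B", "C"]
    )
    pendant = {}
    for u, v, length in tri.edges():
        leaf = tri.leaf_labels.get(u, tri.leaf_labels.get(v))
        pendant[leaf] = length
    closed = {"A": (dab + dac - dbc) / 2, "B": (dab + dbc - dac) / 2,
              "C": (dac + dbc - dab) / 2}
    max_err = max(abs(pendant[x] - closed[x]) for x in closed)
    return {"n_matrices": n_matrices, "n_recovered": recovered,
            "recovery_rate": recovered / n_matrices,
            "three_taxon_max_branch_error": max_err}


# ---------------------------------------------------------------------------
# 6. monophyly recovery


def run_monophyly_recovery(
    seed: int,
    n_replicates: int = 40,
    n_species: int = 3,
    per_species: int = 5,
    interspecies: float = 0.15,
    intraspecies: float = 0.02,
    query_length: int = 800,
) -> dict:
    """Fraction of replicates in which every simulated species forms a
    monophyletic group in the JC+NJ NUMT tree."""
    rng = _rng(seed, 6)
    query = random_query(query_length, rng=rng)
    good = 0
    for _ in range(n_replicates):
        sequences, species_of = plant_multispecies(
            query, n_species, per_species, interspecies, intraspecies, rng
        )
        msa = msa_from_equal_length_sequences(sequences)
        dm = jc_distance(msa, min_shared_sites=100)
        tree = nj_tree(dm)
        good += all(species_monophyly(tree, species_of).values())
    return {"n_replicates": n_replicates, "n_all_monophyletic": good,
            "monophyly_rate": good / n_replicates}
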