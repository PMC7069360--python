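"""Reference-anchored MSA, JC distances, NJ, and monophyly tests."""

import math

import numpy as np
import pytest

from numtscan import (AlignmentHit, GenomeAssembly, QueryGene,
                      induce_reference_msa, is_monophyletic, jc_distance,
                      neighbor_joining, random_query, reverse_complement)
from numtscan.phylo import (InsufficientOverlapError, ReferenceMSA,
                            msa_from_equal_length_sequences, nj_tree)


def trace_hit(sid, qs, qe, ss, subject, strand="+", trace=None):
    trace = trace if trace is not None else "M" * (qe - qs)
    return AlignmentHit(
        query_id="q", scaffold_id=sid, q_start=qs, q_end=qe,
        s_start=ss, s_end=ss + sum(op != "D" for op in trace), strand=strand,
        aln_len=len(trace), identity=1.0, score=float(2 * len(trace)),
        trace=trace, subject_aln=subject,
    )


class TestInduceMSA:
    def test_two_partial_hits_share_query_coordinates(self, query):
        s1 = query.sequence[0:100]
        s2 = query.sequence[50:150]
        msa = induce_reference_msa(
            [trace_hit("a", 0, 100, 0, s1), trace_hit("b", 50, 150, 0, s2)],
            query,
        )
        assert msa.width == query.length
        assert all(len(r) == query.length for r in msa.rows)
        r1, r2 = msa.rows
        assert r1[0:100] == s1 and set(r1[100:]) == {"-"}
        assert r2[50:150] == s2 and set(r2[:50]) == {"-"}
        # columns 50-99 covered by both
        assert "-" not in r1[50:100] and "-" not in r2[50:100]

    def test_insertion_relative_to_query_is_dropped(self, query):
        # 10 matches, 3-base insertion, 10 matches
        subject = query.sequence[0:10] + "AAA" + query.sequence[10:20]
        hit = trace_hit("a", 0, 20, 0, subject, trace="M" * 10 + "I" * 3 + "M" * 10)
        msa = induce_reference_msa([hit], query)
        assert len(msa.rows[0]) == query.length
        assert msa.rows[0][:20] == query.sequence[:20]

    def test_deletion_leaves_gap_columns(self, query):
        subject = query.sequence[0:10] + "---" + query.sequence[13:20]
        hit = trace_hit("a", 0, 20, 0, subject, trace="M" * 10 + "D" * 3 + "M" * 7)
        msa = induce_reference_msa([hit], query)
        assert msa.rows[0][10:13] == "---"

    def test_full_identical_hit_reproduces_query(self, query):
        hit = trace_hit("a", 0, query.length, 0, query.sequence)
        msa = induce_reference_msa([hit], query)
        assert msa.rows[0] == query.sequence

    def test_inconsistent_trace_rejected(self, query):
        bad = trace_hit("a", 0, 50, 0, query.sequence[0:40], trace="M" * 40)
        with pytest.raises(ValueError, match="inconsistent"):
            induce_reference_msa([bad], query)

    def test_traceless_hit_realigned_through_assembly(self, rng):
        """A BLAST-tabular style hit (no column trace) is realigned with
        Smith-Waterman and yields the same row as the built-in search hit."""
        from numtscan import search
        from numtscan.simulate import generate_background

        q = random_query(400, rng=rng, name="q")
        frag, _, _ = __import__("numtscan").mutate_fragment(
            q.sequence[50:350], 0.05, 0.01, rng)
        bg = generate_background(2000, 0.4, rng)
        assembly = GenomeAssembly({"s": bg[:800] + reverse_complement(frag) + bg[800:]})
        (hit,) = search(q, assembly)
        stripped = AlignmentHit(
            query_id=hit.query_id, scaffold_id=hit.scaffold_id,
            q_start=hit.q_start, q_end=hit.q_end,
            s_start=hit.s_start, s_end=hit.s_end, strand=hit.strand,
            aln_len=hit.aln_len, identity=hit.identity, score=hit.score,
        )
        via_trace = induce_reference_msa([hit], q)
        via_realign = induce_reference_msa([stripped], q, assembly)
        mism = sum(
            a != b for a, b in zip(via_trace.rows[0], via_realign.rows[0])
        )
        assert mism <= 2  # boundary wobble only

    def test_row_order_invariance(self, query):
        h1 = trace_hit("a", 0, 100, 0, query.sequence[0:100])
        h2 = trace_hit("b", 50, 150, 0, query.sequence[50:150])
        m12 = induce_reference_msa([h1, h2], query)
        m21 = induce_reference_msa([h2, h1], query)
        assert dict(zip(m12.labels, m12.rows)) == dict(zip(m21.labels, m21.rows))


class TestJCDistance:
    def test_identical_rows_have_zero_distance(self):
        msa = msa_from_equal_length_sequences([("a", "ACGT" * 50), ("b", "ACGT" * 50)])
        dm = jc_distance(msa, min_shared_sites=10)
        assert dm.d[0, 1] == 0.0

    def test_quarter_mismatch_closed_form(self):
        # 400 shared sites, exactly 100 mismatching
        row_a = "A" * 400
        row_b = "C" * 100 + "A" * 300
        dm = jc_distance(
            msa_from_equal_length_sequences([("a", row_a), ("b", row_b)]),
            min_shared_sites=10,
        )
        expected = -0.75 * math.log(1 - (4 / 3) * 0.25)
        assert dm.d[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3041, abs=1e-4)

    def test_saturated_pair_flagged(self):
        row_a = "A" * 400
        row_b = "C" * 300 + "A" * 100  # p = 0.75
        dm = jc_distance(
            msa_from_equal_length_sequences([("a", row_a), ("b", row_b), ("c", row_a)]),
            min_shared_sites=10,
        )
        assert math.isnan(dm.d[0, 1])
        assert ("a", "b") in dm.saturated_pairs
        labels, sub = dm.tree_ready()
        assert set(labels) == {"a", "c"}

    def test_insufficient_overlap_raises(self):
        msa = msa_from_equal_length_sequences(
            [("a", "ACGT" * 10 + "-" * 40), ("b", "-" * 40 + "ACGT" * 10)]
        )
        with pytest.raises(InsufficientOverlapError):
            jc_distance(msa, min_shared_sites=10)

    def test_distance_strictly_increasing_in_p(self):
        prev = -1.0
        for n_mismatch in range(0, 280, 20):
            row_a = "A" * 400
            row_b = "C" * n_mismatch + "A" * (400 - n_mismatch)
            dm = jc_distance(
                msa_from_equal_length_sequences([("a", row_a), ("b", row_b)]),
                min_shared_sites=10,
            )
            assert dm.d[0, 1] > prev
            prev = dm.d[0, 1]

    def test_gap_and_n_sites_excluded_from_shared_count(self):
        msa = msa_from_equal_length_sequences(
            [("a", "ACGTACGTACGTACGTACGN"), ("b", "ACGTACGT----ACGTACGA")]
        )
        dm = jc_distance(msa, min_shared_sites=5)
        assert dm.n_shared[0, 1] == 15
        assert dm.d[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(D, ["A", "B", "C"])
        pendant = {}
        for u, v, length in tree.edges():
            leaf = tree.leaf_labels.get(u, tree.leaf_labels.get(v))
            pendant[leaf] = length
        assert pendant["A"] == pytest.approx(1.0, abs=1e-9)
        assert pendant["B"] == pytest.approx(1.0, abs=1e-9)
        assert pendant["C"] == pytest.approx(2.0, abs=1e-9)

    def test_additive_four_taxon_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(D, ["A", "B", "C", "D"])
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})
        assert not is_monophyletic(tree, {"A", "C"})
        lengths = {}
        for u, v, length in tree.edges():
            leaf = tree.leaf_labels.get(u, tree.leaf_labels.get(v))
            if leaf:
                lengths[leaf] = length
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        ((u, v, length),) = tree.edges()
        assert length == pytest.approx(0.4)
        assert tree.leaves() == {"A", "B"}

    def test_matches_dendropy_nj_on_random_additive_matrices(self, rng):
        import dendropy

        from numtscan.benchmarks import _tree_distances, random_additive_tree

        for _ in range(10):
            n_taxa = int(rng.integers(5, 11))
            adj, labels, leaf_ids = random_additive_tree(n_taxa, rng)
            D = _tree_distances(adj, leaf_ids)
            mine = neighbor_joining(D, labels)
            csv = "," + ",".join(labels) + "\n" + "\n".join(
                labels[i] + "," + ",".join(str(D[i, j]) for j in range(n_taxa))
                for i in range(n_taxa)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=__import__("io").StringIO(csv), delimiter=",")
            their = pdm.nj_tree()
            their.encode_bipartitions()
            tns = their.taxon_namespace
            leafset = frozenset(labels)
            anchor = min(labels)
            theirs = set()
            for bp in their.bipartition_encoding:
                side = frozenset(t.label for t in bp.leafset_taxa(tns))
                if anchor in side:
                    side = frozenset(leafset - side)
                if 1 < len(side) < n_taxa - 1:
                    theirs.add(side)
            ours = {s for s in mine.bipartitions() if 1 < len(s) < n_taxa - 1}
            assert ours == theirs

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["A", "A"])

    def test_nan_matrix_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(D, ["A", "B"])


class TestMonophyly:
    @pytest.fixture()
    def balanced_tree(self):
        # ((a1:1,a2:1):1,(b1:1,b2:1):1) as distances
        D = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float)
        return neighbor_joining(D, ["a1", "a2", "b1", "b2"])

    def test_clade_is_monophyletic(self, balanced_tree):
        assert is_monophyletic(balanced_tree, {"a1", "a2"})

    def test_split_pair_is_not_monophyletic(self, balanced_tree):
        assert not is_monophyletic(balanced_tree, {"a1", "b1"})

    def test_singleton_always_monophyletic(self, balanced_tree):
        assert is_monophyletic(balanced_tree, {"a1"})

    def test_complement_counts_as_monophyletic(self, balanced_tree):
        assert is_monophyletic(balanced_tree, {"a2", "b1", "b2"})

    def test_unknown_label_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="not in tree"):
            is_monophyletic(balanced_tree, {"zz"})

    def test_species_recovered_on_simulated_numts(self, rng):
        from numtscan import plant_multispecies, species_monophyly

        query = random_query(800, rng=rng)
        for _ in range(5):
            seqs, species_of = plant_multispecies(query, 3, 5, 0.15, 0.02, rng)
            dm = jc_distance(
                msa_from_equal_length_sequences(seqs), min_shared_sites=100)
            tree = nj_tree(dm)
            assert all(species_monophyly(tree, species_of).values())
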