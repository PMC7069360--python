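"""Filter semantics, insertion-site merging, extraction, counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from numtscan import (AlignmentHit, FilterParams, GenomeAssembly,
                      count_sites, extract_numt_sequences, filter_hits,
                      merge_insertion_sites, reverse_complement)
from numtscan.benchmarks import filter_boundary_fixture


def make_hit(sid, ss, se, aln_len=None, strand="+", score=None):
    aln_len = aln_len if aln_len is not None else se - ss
    return AlignmentHit(
        query_id="q", scaffold_id=sid, q_start=0, q_end=aln_len,
        s_start=ss, s_end=se, strand=strand, aln_len=aln_len,
        identity=1.0, score=float(score if score is not None else 2 * aln_len),
    )


class TestFilterHits:
    def test_boundary_fixture_ledger(self):
        """Six constructed hits at the criteria boundaries produce exactly the
        forced keep/remove/reason ledger."""
        assembly, hits, expected = filter_boundary_fixture()
        report = filter_hits(hits, assembly)
        assert len(report.records) == len(hits)
        for idx, record in enumerate(report.records):
            want_state, want_reasons = expected[idx]
            assert record.kept == (want_state == "kept"), f"hit {idx}"
            assert set(record.reasons) == want_reasons, f"hit {idx}"
        t = report.tallies
        assert t["input"] == t["kept"] + t["removed"] == 6

    def test_length_boundary_is_strict(self):
        assembly = GenomeAssembly({"s": "A" * 10_000})
        r99 = filter_hits([make_hit("s", 2000, 2099, 99)], assembly).records[0]
        r100 = filter_hits([make_hit("s", 2000, 2100, 100)], assembly).records[0]
        assert not r99.kept and r99.reasons == ("min_length",)
        assert r100.kept

    def test_span_at_95_percent_removed_with_both_reasons(self):
        assembly = GenomeAssembly({"s": "A" * 1000})
        rec = filter_hits([make_hit("s", 0, 950)], assembly).records[0]
        assert not rec.kept
        assert set(rec.reasons) == {"scaffold_span", "edge"}

    def test_interior_mid_size_hit_is_kept(self):
        assembly = GenomeAssembly({"s": "A" * 5000})
        rec = filter_hits([make_hit("s", 2000, 2300)], assembly).records[0]
        assert rec.kept and rec.reasons == ()

    def test_unknown_scaffold_rejected(self):
        assembly = GenomeAssembly({"s": "A" * 5000})
        with pytest.raises(ValueError, match="unknown scaffold"):
            filter_hits([make_hit("sX", 0, 200)], assembly)

    def test_filtering_is_idempotent(self, planted):
        assembly, _, query, _ = planted
        from numtscan import search

        hits = search(query, assembly)
        report = filter_hits(hits, assembly)
        again = filter_hits(report.kept_hits, assembly)
        assert again.tallies["removed"] == 0
        assert again.kept_hits == report.kept_hits

    def test_partition_kept_plus_removed(self, planted):
        assembly, _, query, _ = planted
        from numtscan import search

        hits = search(query, assembly)
        report = filter_hits(hits, assembly)
        assert len(report.kept_hits) + len(report.removed_hits) == len(hits)

    @given(
        min_len=st.integers(50, 400),
        edge_tol=st.integers(0, 100),
        span=st.floats(0.5, 1.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_tightening_thresholds_never_keeps_more(self, min_len, edge_tol, span):
        assembly = GenomeAssembly({"s": "A" * 2000})
        rng = np.random.default_rng(42)
        hits = []
        for _ in range(30):
            ss = int(rng.integers(0, 1800))
            se = ss + int(rng.integers(20, 2000 - ss))
            hits.append(make_hit("s", ss, se))
        base = FilterParams()
        tight = FilterParams(
            min_len=max(base.min_len, min_len),
            max_span_frac=min(base.max_span_frac, span),
            edge_tol=max(base.edge_tol, edge_tol),
        )
        n_base = filter_hits(hits, assembly, base).tallies["kept"]
        n_tight = filter_hits(hits, assembly, tight).tallies["kept"]
        assert n_tight <= n_base


def brute_force_merge(intervals, merge_gap):
    """O(n^2) transitive closure over the 'gap <= merge_gap' relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        (s1, e1), (s2, e2) = intervals[i], intervals[j]
        gap = max(s1, s2) - min(e1, e2)
        if gap <= merge_gap:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )


class TestMergeInsertionSites:
    def test_gap_within_merge_distance_joins(self):
        hits = [make_hit("s", 100, 400), make_hit("s", 900, 1200)]
        loci = merge_insertion_sites(hits, FilterParams(merge_gap=1000))
        assert len(loci) == 1 and loci[0].interval == (100, 1200)

    def test_gap_beyond_merge_distance_splits(self):
        hits = [make_hit("s", 100, 400), make_hit("s", 900, 1200)]
        loci = merge_insertion_sites(hits, FilterParams(merge_gap=100))
        assert [l.interval for l in loci] == [(100, 400), (900, 1200)]

    def test_different_scaffolds_never_merge(self):
        hits = [make_hit("s1", 100, 400), make_hit("s2", 100, 400)]
        assert len(merge_insertion_sites(hits, FilterParams(merge_gap=10**6))) == 2

    def test_strands_merge_together(self):
        hits = [make_hit("s", 100, 400, strand="+", score=100),
                make_hit("s", 500, 800, strand="-", score=999)]
        loci = merge_insertion_sites(hits, FilterParams(merge_gap=1000))
        assert len(loci) == 1
        assert loci[0].strand == "-"  # strand of the best-scoring member

    @pytest.mark.parametrize("merge_gap", [0, 50, 500, 5000])
    def test_matches_brute_force_oracle(self, merge_gap, rng):
        for _ in range(10):
            n = int(rng.integers(1, 25))
            intervals = []
            for _ in range(n):
                ss = int(rng.integers(0, 20_000))
                intervals.append((ss, ss + int(rng.integers(1, 2000))))
            hits = [make_hit("s", ss, se) for ss, se in intervals]
            loci = merge_insertion_sites(hits, FilterParams(merge_gap=merge_gap))
            assert [l.interval for l in loci] == brute_force_merge(intervals, merge_gap)
            # loci are pairwise separated by more than merge_gap
            for a, b in zip(loci, loci[1:]):
                assert b.start - a.end > merge_gap

    def test_count_invariant_to_input_order(self, rng):
        hits = [make_hit("s", int(ss), int(ss) + 300)
                for ss in rng.integers(0, 50_000, size=15)]
        base = merge_insertion_sites(hits, FilterParams())
        perm = list(hits)
        rng.shuffle(perm)
        shuffled = merge_insertion_sites(perm, FilterParams())
        assert [l.interval for l in base] == [l.interval for l in shuffled]


class TestExtractAndCount:
    def test_zero_divergence_plus_strand_plant_roundtrips(self, query):
        from numtscan import InsertionSpec, SimConfig, plant_numts, search

        config = SimConfig(
            n_scaffolds=1, scaffold_length_range=(6000, 6000),
            insertions=[InsertionSpec("interior", (1534, 1534), 0.0, 0.0, "+")],
            seed=13,
        )
        assembly, truths = plant_numts(config, query)
        hits = search(query, assembly)
        loci = merge_insertion_sites(filter_hits(hits, assembly).kept_hits)
        (label, seq), = extract_numt_sequences(assembly, loci)
        assert seq == query.sequence

    def test_minus_strand_extraction_reverse_complements(self):
        from Bio.Seq import Seq

        scaffold = "AAAA" + "ACGTTGCA" + "TTTT"
        assembly = GenomeAssembly({"s": scaffold})
        hit = make_hit("s", 4, 12, strand="-")
        loci = merge_insertion_sites([hit])
        (label, seq), = extract_numt_sequences(assembly, loci)
        assert seq == str(Seq("ACGTTGCA").reverse_complement())
        assert label == "s:5-12(-)"

    def test_width_one_locus(self):
        assembly = GenomeAssembly({"s": "ACGT"})
        hit = make_hit("s", 2, 3)
        (_, seq), = extract_numt_sequences(assembly, merge_insertion_sites([hit]))
        assert seq == "G"

    def test_out_of_bounds_locus_rejected(self):
        assembly = GenomeAssembly({"s": "ACGT"})
        locus = merge_insertion_sites([make_hit("s", 2, 3)])[0]
        locus.end = 99
        with pytest.raises(ValueError):
            extract_numt_sequences(assembly, [locus])

    def test_count_sites_totals_and_order_invariance(self):
        assert count_sites([]) == {"total": 0, "per_scaffold": {}}
        hits = [make_hit("s2", 0, 300), make_hit("s1", 0, 300),
                make_hit("s1", 5000, 5300)]
        loci = merge_insertion_sites(hits, FilterParams(merge_gap=100))
        counts = count_sites(loci)
        assert counts["total"] == 3
        assert counts["per_scaffold"] == {"s1": 2, "s2": 1}
        assert count_sites(loci[::-1])["total"] == 3
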