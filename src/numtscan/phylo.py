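"""NUMT phylogeny: reference-anchored MSA, JC69 distances, neighbor joining.

Instead of a de-novo multiple aligner, the MSA is induced from each NUMT's
pairwise alignment to the query gene: every row lives in query coordinates
(length Lq), residues from match/mismatch columns are copied in, deletions in
the NUMT leave gaps, and insertions relative to the query are dropped. This
makes the alignment deterministic and lets hits from different scaffolds (or
simulated species) share one coordinate system.

Distances are Jukes-Cantor corrected, d = -(3/4) ln(1 - (4/3) p), over the
sites where both rows are resolved; the tree is Saitou-Nei neighbor joining
with the Studier-Keppler Q criterion. Per-species monophyly is decided on the
unrooted tree's bipartitions. The extracted NUMT FASTA is also exported so
external aligners and ML tree programs can be run for replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .call import NumtLocus
from .io import AlignmentHit, GenomeAssembly, QueryGene, reverse_complement, sanitize_label


class InsufficientOverlapError(ValueError):
    """All row pairs lack enough shared sites for a distance."""


# ---------------------------------------------------------------------------
# reference-anchored MSA


@dataclass
class ReferenceMSA:
    """Alignment in query coordinates: every row has length Lq."""

    query_id: str
    width: int
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        for label, row in zip(self.labels, self.rows):
            if len(row) != self.width:
                raise ValueError(f"row {label!r} has length {len(row)} != {self.width}")

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(zip(self.labels, self.rows), path)


def _row_from_trace(q_start: int, q_end: int, trace: str, subject_aln: str,
                    width: int, row: list[str]) -> None:
    qi = q_start
    for op, ch in zip(trace, subject_aln):
        if op == "M":
            if row[qi] == "-":
                row[qi] = ch
            qi += 1
        elif op == "D":  # gap in the NUMT: reference position uncovered
            qi += 1
        # 'I': insertion relative to the query, dropped from the MSA
    if qi != q_end:
        raise ValueError(
            f"trace inconsistent with query interval: ends at {qi}, expected {q_end}"
        )


def _aligned_hit(hit: AlignmentHit, query: QueryGene,
                 assembly: GenomeAssembly | None) -> AlignmentHit:
    """Return a hit carrying a column trace, realigning via Smith-Waterman
    when the input (e.g. BLAST tabular) has none."""
    if hit.trace is not None and hit.subject_aln is not None:
        return hit
    if assembly is None:
        raise ValueError(
            "hit has no column trace; pass the assembly so it can be realigned"
        )
    from .search import smith_waterman

    subject = assembly.sequence(hit.scaffold_id)[hit.s_start:hit.s_end]
    if hit.strand == "-":
        subject = reverse_complement(subject)
    aln = smith_waterman(query.sequence, subject)
    realigned = AlignmentHit(
        query_id=query.id, scaffold_id=hit.scaffold_id,
        q_start=aln.q_start, q_end=aln.q_end,
        s_start=hit.s_start, s_end=hit.s_end, strand=hit.strand,
        aln_len=aln.aln_len, identity=aln.identity, score=aln.score,
        gaps=aln.gaps, trace=aln.trace, subject_aln=aln.subject_aln,
    )
    return realigned


def induce_reference_msa(
    items: Sequence[AlignmentHit | NumtLocus],
    query: QueryGene,
    assembly: GenomeAssembly | None = None,
) -> ReferenceMSA:
    """One MSA row per hit or locus. A locus row overlays its member hits,
    best score first, so overlapping members never overwrite each other."""
    width = query.length
    labels: list[str] = []
    rows: list[str] = []
    for item in items:
        row = ["-"] * width
        if isinstance(item, NumtLocus):
            label = item.label
            members = sorted(
                item.members, key=lambda h: (-h.score, h.s_start, h.q_start)
            )
            for member in members:
                h = _aligned_hit(member, query, assembly)
                _row_from_trace(h.q_start, h.q_end, h.trace, h.subject_aln, width, row)
        else:
            h = _aligned_hit(item, query, assembly)
            label = f"{h.scaffold_id}:{h.s_start + 1}-{h.s_end}({h.strand})"
            _row_from_trace(h.q_start, h.q_end, h.trace, h.subject_aln, width, row)
        labels.append(label)
        rows.append("".join(row))
    return ReferenceMSA(query_id=query.id, width=width, labels=labels, rows=rows)


def msa_from_equal_length_sequences(
    sequences: Sequence[tuple[str, str]], query_id: str = "query"
) -> ReferenceMSA:
    """Wrap already-aligned (or indel-free, query-length) sequences as an MSA."""
    labels = [name for name, _ in sequences]
    rows = [seq for _, seq in sequences]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("sequences differ in length; align them to the query first")
    return ReferenceMSA(query_id=query_id, width=widths.pop(), labels=labels, rows=rows)


# ---------------------------------------------------------------------------
# Jukes-Cantor distances

_SATURATION_P = 0.75

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray          # JC distances; NaN where flagged
    p: np.ndarray          # raw mismatch proportions
    n_shared: np.ndarray   # shared resolved sites per pair
    excluded_pairs: set[tuple[str, str]] = field(default_factory=set)
    saturated_pairs: set[tuple[str, str]] = field(default_factory=set)

    def tree_ready(self) -> tuple[list[str], np.ndarray]:
        """Largest label subset with all-finite distances: greedily drop the
        label with the most flagged pairs (ties by label order)."""
        active = list(range(len(self.labels)))
        while True:
            sub = self.d[np.ix_(active, active)]
            bad = np.isnan(sub)
            if not bad.any():
                break
            counts = bad.sum(axis=1)
            worst = int(np.argmax(counts))  # first max = earliest label
            del active[worst]
            if len(active) < 2:
                raise InsufficientOverlapError(
                    "insufficient overlap: no pair of rows shares enough sites"
                )
        return [self.labels[i] for i in active], self.d[np.ix_(active, active)]


def jc_distance(msa: ReferenceMSA, min_shared_sites: int = 100) -> DistanceMatrix:
    """Pairwise JC69 distances over jointly resolved (non-gap, non-N) sites.

    Pairs with fewer than min_shared_sites shared sites, or with p at or past
    the 0.75 saturation boundary, are flagged (NaN) and excluded from tree
    building.
    """
    n = len(msa.rows)
    if n < 2:
        raise ValueError("need at least two rows")
    codes = np.vstack([
        _CODE[np.frombuffer(r.encode("ascii"), dtype=np.uint8)] for r in msa.rows
    ])
    resolved = codes < 4
    d = np.zeros((n, n))
    p = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    excluded: set[tuple[str, str]] = set()
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            both = resolved[i] & resolved[j]
            nij = int(both.sum())
            shared[i, j] = shared[j, i] = nij
            if nij < min_shared_sites:
                excluded.add((msa.labels[i], msa.labels[j]))
                d[i, j] = d[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            pij = float((codes[i][both] != codes[j][both]).sum()) / nij
            p[i, j] = p[j, i] = pij
            if pij >= _SATURATION_P:
                saturated.add((msa.labels[i], msa.labels[j]))
                d[i, j] = d[j, i] = np.nan
            else:
                dij = -0.75 * math.log(1.0 - 4.0 * pij / 3.0)
                d[i, j] = d[j, i] = dij
    if np.isnan(d[np.triu_indices(n, 1)]).all():
        raise InsufficientOverlapError(
            "insufficient overlap: no pair of rows shares enough sites"
        )
    return DistanceMatrix(
        labels=list(msa.labels), d=d, p=p, n_shared=shared,
        excluded_pairs=excluded, saturated_pairs=saturated,
    )


# ---------------------------------------------------------------------------
# unrooted trees


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map; leaves carry labels."""

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    clamped_deficit: float = 0.0  # total negative branch length clamped to 0

    def leaves(self) -> set[str]:
        return set(self.leaf_labels.values())

    def _side_leaves(self, start: int, blocked: int) -> frozenset[str]:
        seen = {blocked, start}
        stack = [start]
        out = set()
        while stack:
            node = stack.pop()
            if node in self.leaf_labels:
                out.add(self.leaf_labels[node])
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, length in nbrs:
                if u < v:
                    out.append((u, v, length))
        return out

    def bipartitions(self, include_trivial: bool = True) -> set[frozenset[str]]:
        """One leaf-set side per edge, canonicalised to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaves()
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()
        for u, v, _ in self.edges():
            side = self._side_leaves(v, u)
            if anchor in side:
                side = frozenset(all_leaves - side)
            if not side or len(side) == len(all_leaves):
                continue
            if not include_trivial and min(len(side), len(all_leaves) - len(side)) < 2:
                continue
            parts.add(side)
        return parts

    def newick(self) -> str:
        nodes = list(self.adjacency)
        internal = [n for n in nodes if n not in self.leaf_labels]
        root = internal[0] if internal else nodes[0]

        def render(node: int, parent: int | None) -> str:
            children = [
                (nbr, length) for nbr, length in self.adjacency[node] if nbr != parent
            ]
            if not children:
                return sanitize_label(self.leaf_labels[node])
            inner = ",".join(
                f"{render(nbr, node)}:{length:.6g}" for nbr, length in children
            )
            name = (
                sanitize_label(self.leaf_labels[node])
                if node in self.leaf_labels else ""
            )
            return f"({inner}){name}"

        return render(root, None) + ";"


def neighbor_joining(matrix: np.ndarray, labels: Sequence[str]) -> UnrootedTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Deterministic: ties in Q are broken by the (sorted) label pair. Negative
    branch lengths are clamped to zero and the total deficit recorded on the
    tree. Exactly recovers additive matrices.
    """
    labels = list(labels)
    D = np.asarray(matrix, dtype=float).copy()
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(D, D.T, equal_nan=False):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN; drop flagged pairs first")
    if len(set(labels)) != n:
        raise ValueError("duplicate leaf labels")
    if n == 0:
        raise ValueError("no labels")

    adjacency: dict[int, list[tuple[int, float]]] = {}
    leaf_labels: dict[int, str] = {}
    deficit = 0.0

    def add_edge(u: int, v: int, length: float) -> None:
        nonlocal deficit
        if length < 0:
            deficit += -length
            length = 0.0
        adjacency.setdefault(u, []).append((v, length))
        adjacency.setdefault(v, []).append((u, length))

    node_ids = list(range(n))
    for i, label in enumerate(labels):
        leaf_labels[i] = label
        adjacency[i] = []
    next_id = n
    # sort_key orders tie-broken pairs by current cluster label
    names = list(labels)

    if n == 1:
        return UnrootedTree(adjacency=adjacency, leaf_labels=leaf_labels)
    if n == 2:
        add_edge(0, 1, float(D[0, 1]))
        return UnrootedTree(adjacency=adjacency, leaf_labels=leaf_labels)

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        # floating summation order makes Q asymmetric in the last bit;
        # decide on the upper triangle only
        Q[~np.triu(np.ones((r, r), dtype=bool), 1)] = np.inf
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        best_pair = min(
            (tuple(sorted((names[active[i]], names[active[j]]))), i, j)
            for i, j in ties
        )
        _, ai, aj = best_pair
        i_id, j_id = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        adjacency[u] = []
        names.append(f"({names[i_id]},{names[j_id]})")
        add_edge(u, i_id, float(li))
        add_edge(u, j_id, float(lj))
        # distances from u to the remaining clusters
        newD = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i_id, j_id):
                continue
            duk = 0.5 * (D[i_id, k] + D[j_id, k] - dij)
            newD[u, k] = newD[k, u] = duk
        D = newD
        active = [k for k in active if k not in (i_id, j_id)] + [u]

    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        u = next_id
        adjacency[u] = []
        add_edge(u, a, float(la))
        add_edge(u, b, float(lb))
        add_edge(u, c, float(lc))
    else:  # two clusters left (can happen only when n == 2, handled above)
        a, b = active
        add_edge(a, b, float(D[a, b]))

    tree = UnrootedTree(adjacency=adjacency, leaf_labels=leaf_labels)
    tree.clamped_deficit = deficit
    return tree


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Neighbor joining on the tree-ready subset of a DistanceMatrix."""
    labels, matrix = dm.tree_ready()
    return neighbor_joining(matrix, labels)


def is_monophyletic(tree: UnrootedTree, label_subset: Iterable[str]) -> bool:
    """True iff the subset (or its complement) is one side of a bipartition
    of the unrooted tree. Singletons are trivially monophyletic."""
    subset = frozenset(label_subset)
    leaves = tree.leaves()
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if not 0 < len(subset) < len(leaves):
        raise ValueError("subset must be a proper non-empty subset of the leaves")
    complement = frozenset(leaves - subset)
    for part in tree.bipartitions(include_trivial=True):
        if part == subset or part == complement:
            return True
    return False


def species_monophyly(
    tree: UnrootedTree, species_of: Mapping[str, str]
) -> dict[str, bool]:
    """Monophyly verdict per species over the leaves present in the tree."""
    leaves = tree.leaves()
    groups: dict[str, set[str]] = {}
    for label in leaves:
        species = species_of.get(label)
        if species is not None:
            groups.setdefault(species, set()).add(label)
    verdicts: dict[str, bool] = {}
    for species, members in sorted(groups.items()):
        if len(members) == len(leaves):
            verdicts[species] = True  # everything is one species
        else:
            verdicts[species] = is_monophyletic(tree, members)
    return verdicts
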