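"""NUMT calling: exclusion filters, insertion-site merging, extraction.

Three criteria remove homology hits that are unlikely to be genuine nuclear
insertions of the mitochondrial query:

  a. ``min_length``   — alignment shorter than 100 columns (strict <).
  b. ``scaffold_span``— the hit's subject span covers >= 95% of its scaffold,
                        the signature of a mitochondrial contamination
                        scaffold rather than a nuclear insertion.
  c. ``edge``         — the hit abuts a scaffold edge (within edge_tol bp),
                        where a truncated alignment cannot be distinguished
                        from an assembly artifact.

A removed hit records every criterion that fired. Surviving hits on the same
scaffold are merged transitively (gap <= merge_gap, strand-agnostic) into
insertion sites — the countable unit of the analysis — and the site sequences
are extracted in query orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import AlignmentHit, GenomeAssembly, reverse_complement

REASONS = ("min_length", "scaffold_span", "edge")


@dataclass(frozen=True)
class FilterParams:
    min_len: int = 100
    max_span_frac: float = 0.95
    edge_tol: int = 10
    merge_gap: int = 1000

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0 < self.max_span_frac <= 1:
            raise ValueError("max_span_frac must lie in (0, 1]")
        if self.edge_tol < 0 or self.merge_gap < 0:
            raise ValueError("edge_tol and merge_gap must be >= 0")


@dataclass
class FilterRecord:
    hit: AlignmentHit
    kept: bool
    reasons: tuple[str, ...]


@dataclass
class FilterReport:
    records: list[FilterRecord]
    params: FilterParams

    @property
    def kept_hits(self) -> list[AlignmentHit]:
        return [r.hit for r in self.records if r.kept]

    @property
    def removed_hits(self) -> list[AlignmentHit]:
        return [r.hit for r in self.records if not r.kept]

    @property
    def tallies(self) -> dict[str, int]:
        t = {reason: 0 for reason in REASONS}
        for r in self.records:
            for reason in r.reasons:
                t[reason] += 1
        t["kept"] = sum(r.kept for r in self.records)
        t["removed"] = sum(not r.kept for r in self.records)
        t["input"] = len(self.records)
        return t

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {
                "scaffold_id": r.hit.scaffold_id,
                "s_start": r.hit.s_start, "s_end": r.hit.s_end,
                "strand": r.hit.strand, "aln_len": r.hit.aln_len,
                "identity": round(r.hit.identity, 6), "score": r.hit.score,
                "kept": r.kept,
                "reasons": ",".join(r.reasons) if r.reasons else ".",
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_hits(
    hits: Iterable[AlignmentHit],
    assembly: GenomeAssembly,
    params: FilterParams | None = None,
) -> FilterReport:
    """Apply the three exclusion criteria; a hit is removed iff any fires,
    and all firing criteria are recorded (evaluation order a, b, c)."""
    params = params if params is not None else FilterParams()
    records: list[FilterRecord] = []
    for hit in hits:
        if hit.scaffold_id not in assembly:
            raise ValueError(f"hit references unknown scaffold {hit.scaffold_id!r}")
        slen = assembly.length(hit.scaffold_id)
        reasons: list[str] = []
        if hit.aln_len < params.min_len:
            reasons.append("min_length")
        if hit.subject_span / slen >= params.max_span_frac:
            reasons.append("scaffold_span")
        if hit.s_start <= params.edge_tol or hit.s_end >= slen - params.edge_tol:
            reasons.append("edge")
        records.append(FilterRecord(hit=hit, kept=not reasons, reasons=tuple(reasons)))
    return FilterReport(records=records, params=params)


@dataclass
class NumtLocus:
    """A merged insertion site: the maximal run of kept hits on one scaffold
    with inter-hit gaps <= merge_gap."""

    scaffold_id: str
    start: int
    end: int
    strand: str  # strand of the best-scoring member
    members: list[AlignmentHit] = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def best_hit(self) -> AlignmentHit:
        return max(self.members, key=lambda h: (h.score, h.subject_span, -h.s_start))

    @property
    def best_identity(self) -> float:
        return max(h.identity for h in self.members)

    @property
    def best_score(self) -> float:
        return max(h.score for h in self.members)

    @property
    def label(self) -> str:
        """1-based inclusive display label, e.g. 'scaffold_3:201-500(+)'."""
        return f"{self.scaffold_id}:{self.start + 1}-{self.end}({self.strand})"


def merge_insertion_sites(
    kept_hits: Iterable[AlignmentHit],
    params: FilterParams | None = None,
) -> list[NumtLocus]:
    """Transitive, strand-agnostic merge of hits on the same scaffold whose
    interval gap is <= merge_gap; result is order-invariant and sorted."""
    params = params if params is not None else FilterParams()
    by_scaffold: dict[str, list[AlignmentHit]] = {}
    for h in kept_hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)
    loci: list[NumtLocus] = []
    for sid in sorted(by_scaffold):
        group = sorted(by_scaffold[sid], key=lambda h: (h.s_start, h.s_end))
        current: list[AlignmentHit] = []
        cur_end = None
        for h in group:
            if current and h.s_start - cur_end > params.merge_gap:
                loci.append(_finish_locus(sid, current))
                current = []
                cur_end = None
            current.append(h)
            cur_end = h.s_end if cur_end is None else max(cur_end, h.s_end)
        if current:
            loci.append(_finish_locus(sid, current))
    loci.sort(key=lambda l: (l.scaffold_id, l.start, l.end))
    return loci


def _finish_locus(scaffold_id: str, members: list[AlignmentHit]) -> NumtLocus:
    locus = NumtLocus(
        scaffold_id=scaffold_id,
        start=min(h.s_start for h in members),
        end=max(h.s_end for h in members),
        strand="+",
        members=list(members),
    )
    locus.strand = locus.best_hit.strand
    return locus


def extract_numt_sequences(
    assembly: GenomeAssembly,
    loci: Sequence[NumtLocus],
) -> list[tuple[str, str]]:
    """Slice each locus from its scaffold; minus-strand loci are
    reverse-complemented so every output reads in query orientation."""
    out: list[tuple[str, str]] = []
    for locus in loci:
        slen = assembly.length(locus.scaffold_id)
        if not (0 <= locus.start < locus.end <= slen):
            raise ValueError(
                f"locus {locus.label} outside scaffold bounds [0,{slen})"
            )
        seq = assembly.sequence(locus.scaffold_id)[locus.start:locus.end]
        if locus.strand == "-":
            seq = reverse_complement(seq)
        out.append((locus.label, seq))
    return out


def count_sites(loci: Sequence[NumtLocus]) -> dict:
    """Total insertion-site count plus a per-scaffold table (sorted by id)."""
    per_scaffold: dict[str, int] = {}
    for locus in loci:
        per_scaffold[locus.scaffold_id] = per_scaffold.get(locus.scaffold_id, 0) + 1
    return {
        "total": len(loci),
        "per_scaffold": dict(sorted(per_scaffold.items())),
    }
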