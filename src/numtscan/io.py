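"""Readers and writers for the external formats the pipeline touches.

One coordinate convention holds everywhere inside the package: 0-based,
half-open intervals on the forward strand of the named sequence. Conversions
to and from 1-based inclusive conventions (BLAST tabular, display labels)
happen only in this module, at the format boundary.

Formats handled: FASTA (read/write, via Biopython), BLAST 12-column tabular
"outfmt 6" (read/write), BED6 (read/write), Newick (write), TSV hit and
filter tables (write).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastaParseError(ValueError):
    """Raised for unreadable or non-nucleotide FASTA input."""


class BlastTabError(ValueError):
    """Raised for malformed or inconsistent BLAST tabular rows."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_IUPAC_NUC = set("ACGTUNRYSWKMBDHV-.")


def sanitize_sequence(raw: str) -> str:
    """Uppercase, U->T, anything outside {A,C,G,T,N} -> N.

    Rejects records that are not nucleotide-dominant (fewer than 80% of
    residues in the IUPAC nucleotide alphabet before masking), which catches
    protein FASTA handed in by mistake; IUPAC ambiguity codes are accepted
    and masked to N.
    """
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FastaParseError("empty sequence record")
    n_ok = sum(c in _IUPAC_NUC for c in seq)
    if n_ok / len(seq) < 0.8:
        raise FastaParseError(
            "sequence is not nucleotide-dominant "
            f"({n_ok}/{len(seq)} residues in the IUPAC nucleotide alphabet)"
        )
    return "".join(c if c in _VALID else "N" for c in seq)


@dataclass
class GenomeAssembly:
    """Named scaffolds with their sequences; the coordinate frame for hits."""

    scaffolds: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise ValueError(f"scaffold {sid!r} has empty sequence")

    def ids(self) -> list[str]:
        return list(self.scaffolds)

    def sequence(self, scaffold_id: str) -> str:
        return self.scaffolds[scaffold_id]

    def length(self, scaffold_id: str) -> int:
        return len(self.scaffolds[scaffold_id])

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def __len__(self) -> int:
        return len(self.scaffolds)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


@dataclass
class QueryGene:
    """The mitochondrial query gene (cox1 in the motivating analyses)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("query sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """One local alignment (HSP) of the query against a scaffold.

    Intervals are 0-based half-open on the forward strand of each sequence.
    ``trace`` is a CIGAR-like column string in query-forward order:
    'M' = match/mismatch column, 'I' = gap in the query (extra scaffold
    residue), 'D' = gap in the scaffold (query residue unmatched).
    ``subject_aln`` holds the scaffold residues in query orientation, one
    character per trace column, '-' at D columns. Both are None for hits
    ingested from BLAST tabular files, which carry no column-level detail.
    """

    query_id: str
    scaffold_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aln_len: int
    identity: float
    score: float
    gaps: int = 0
    trace: str | None = None
    subject_aln: str | None = None
    evalue: float | None = None

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def subject_span(self) -> int:
        return self.s_end - self.s_start

    def validate(self, assembly: GenomeAssembly, query: QueryGene) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.q_start < self.q_end <= query.length):
            raise ValueError(f"query interval {self.q_interval} outside [0,{query.length})")
        slen = assembly.length(self.scaffold_id)
        if not (0 <= self.s_start < self.s_end <= slen):
            raise ValueError(
                f"scaffold interval {self.s_interval} outside {self.scaffold_id} [0,{slen})"
            )
        if self.aln_len < max(self.q_end - self.q_start, self.s_end - self.s_start):
            raise ValueError("alignment length shorter than either interval")
        if abs(self.identity * self.aln_len - round(self.identity * self.aln_len)) > 0.5:
            raise ValueError("identity inconsistent with integer match count")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a nucleotide FASTA into ordered (id, sequence) pairs.

    Ids are the first whitespace-delimited header token. Sequences are
    sanitized (uppercase, U->T, non-ACGTN masked to N). Duplicate ids and
    empty files raise FastaParseError.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaParseError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            try:
                seq = sanitize_sequence(str(rec.seq))
            except FastaParseError as exc:
                raise FastaParseError(f"record {rec.id!r}: {exc}") from exc
            records.append((rec.id, seq))
    if not records:
        raise FastaParseError(f"no FASTA records in {path}")
    return records


def load_assembly(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly(dict(read_fasta(path)))


def load_query(path: str | Path) -> QueryGene:
    records = read_fasta(path)
    rec_id, seq = records[0]
    return QueryGene(rec_id, seq)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecs, handle, "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_OUTFMT6_COLS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tab(
    path: str | Path,
    assembly: GenomeAssembly,
    query: QueryGene,
) -> list[AlignmentHit]:
    """Ingest a 12-column BLAST tabular file as AlignmentHits.

    1-based inclusive coordinates become 0-based half-open; rows with
    sstart > send become strand '-' with the scaffold interval normalised to
    forward orientation. pident/100 becomes identity. Column traces are
    unavailable from this format and are left as None. The E-value is carried
    as metadata only; it plays no role in filtering.
    """
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastTabError(
                    f"{path}, row {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            (qseqid, sseqid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields[:12]
            if sseqid not in assembly:
                raise BlastTabError(
                    f"{path}, row {lineno}: unknown scaffold id {sseqid!r}"
                )
            try:
                qs, qe = int(qstart) - 1, int(qend)
                ss_raw, se_raw = int(sstart), int(send)
                aln_len = int(length)
                ident = float(pident) / 100.0
                n_gapopen = int(gapopen)
                ev = float(evalue)
                score = float(bitscore)
            except ValueError as exc:
                raise BlastTabError(f"{path}, row {lineno}: {exc}") from exc
            if ss_raw > se_raw:
                strand = "-"
                ss, se = se_raw - 1, ss_raw
            else:
                strand = "+"
                ss, se = ss_raw - 1, se_raw
            hit = AlignmentHit(
                query_id=qseqid, scaffold_id=sseqid,
                q_start=qs, q_end=qe, s_start=ss, s_end=se,
                strand=strand, aln_len=aln_len, identity=ident,
                score=score, gaps=n_gapopen, evalue=ev,
            )
            try:
                hit.validate(assembly, query)
            except ValueError as exc:
                raise BlastTabError(f"{path}, row {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Export hits in the 12-column outfmt-6 dialect for interoperability."""
    with open(path, "w") as handle:
        for h in hits:
            matches = round(h.identity * h.aln_len)
            if h.trace is not None:
                gap_cols = sum(op != "M" for op in h.trace)
                gapopen = len(re.findall(r"(?:I+|D+)", h.trace))
                mismatch = h.aln_len - matches - gap_cols
            else:
                gapopen = h.gaps
                mismatch = max(h.aln_len - matches - h.gaps, 0)
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            evalue = h.evalue if h.evalue is not None else 0.0
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.scaffold_id, f"{h.identity * 100:.3f}",
                        h.aln_len, mismatch, gapopen,
                        h.q_start + 1, h.q_end, sstart, send,
                        f"{evalue:.2g}", f"{h.score:g}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str


def write_bed(records: Iterable, path: str | Path,
              assembly: GenomeAssembly | None = None) -> None:
    """Write BED6 lines. Records need chrom/start/end/name/score/strand or the
    NumtLocus-compatible attributes (scaffold_id, interval, identity)."""
    with open(path, "w") as handle:
        for rec in records:
            if isinstance(rec, BedRecord):
                chrom, start, end = rec.chrom, rec.start, rec.end
                name, score, strand = rec.name, rec.score, rec.strand
            else:  # NumtLocus duck-typing
                chrom, start, end = rec.scaffold_id, rec.start, rec.end
                name, strand = rec.label, rec.strand
                score = round(100 * rec.best_identity)
            if start < 0 or end <= start:
                raise ValueError(f"bad BED interval [{start},{end}) for {chrom}")
            if assembly is not None and end > assembly.length(chrom):
                raise ValueError(
                    f"interval [{start},{end}) exceeds scaffold {chrom}"
                )
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    records: list[BedRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}, row {lineno}: BED6 needs 6 columns")
            records.append(
                BedRecord(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    name=fields[3], score=int(round(float(fields[4]))),
                    strand=fields[5],
                )
            )
    return records


# ---------------------------------------------------------------------------
# Newick

_NEWICK_UNSAFE = re.compile(r"[\s,:;()\[\]']")


def sanitize_label(label: str) -> str:
    """Replace Newick-reserved characters with '_' (documented rule)."""
    return _NEWICK_UNSAFE.sub("_", label)


def write_newick(tree, path: str | Path) -> None:
    """Serialise an UnrootedTree (phylo module) as Newick with branch lengths."""
    with open(path, "w") as handle:
        handle.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# TSV tables

_HIT_COLUMNS = [
    "query_id", "scaffold_id", "q_start", "q_end", "s_start", "s_end",
    "strand", "aln_len", "identity", "score", "gaps", "trace",
]


def write_hits_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "query_id": h.query_id, "scaffold_id": h.scaffold_id,
            "q_start": h.q_start, "q_end": h.q_end,
            "s_start": h.s_start, "s_end": h.s_end, "strand": h.strand,
            "aln_len": h.aln_len, "identity": round(h.identity, 6),
            "score": h.score, "gaps": h.gaps,
            "trace": h.trace if h.trace is not None else ".",
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)
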