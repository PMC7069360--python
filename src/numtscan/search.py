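"""Seed-and-extend local alignment of the query gene against an assembly.

This is a self-contained stand-in for a blastn run: exact k-mer seeds on both
strands, gapped x-drop extension under affine gap costs, a score floor, and
per-scaffold-and-strand deduplication of overlapping hits. A full
Smith-Waterman (Gotoh three-matrix) implementation is provided as the exact
verification oracle for the heuristic path.

Scoring follows the blastn defaults: match +2, mismatch -3, and a gap of
length L costs gap_open + L * gap_extend (so a perfect 200 bp copy scores
400). N never counts as a match, and seeds containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AlignmentHit, GenomeAssembly, QueryGene, reverse_complement

_NEG = -(1 << 40)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """blastn-like scoring; gap penalties are positive and subtracted."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if not self.gap_open >= self.gap_extend >= 1:
            raise ValueError("need gap_open >= gap_extend >= 1")


@dataclass(frozen=True)
class SearchParams:
    k: int = 11
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    x_drop: int = 50
    score_min: int = 60


@dataclass
class SeedIndex:
    """Exact k-mer positions on the query, forward and reverse-complement."""

    k: int
    query_len: int
    fwd: dict[int, np.ndarray]
    rev: dict[int, np.ndarray]
    codes: np.ndarray  # sorted union of keys, for fast membership tests


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-windows plus a validity mask (no N)."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = enc[j:j + n]
        codes = codes * 4 + window
        valid &= window < 4
    return codes, valid


def _positions_by_code(enc: np.ndarray, k: int) -> dict[int, np.ndarray]:
    codes, valid = _kmer_codes(enc, k)
    table: dict[int, list[int]] = {}
    for pos in np.nonzero(valid)[0]:
        table.setdefault(int(codes[pos]), []).append(int(pos))
    return {c: np.asarray(p, dtype=np.int64) for c, p in table.items()}


def build_seed_index(query: QueryGene, k: int) -> SeedIndex:
    if not 4 <= k <= 15:
        raise ValueError("k must lie in [4, 15]")
    if k > query.length:
        raise ValueError("k exceeds query length")
    fwd = _positions_by_code(_encode(query.sequence), k)
    rev = _positions_by_code(_encode(reverse_complement(query.sequence)), k)
    codes = np.array(sorted(set(fwd) | set(rev)), dtype=np.int64)
    return SeedIndex(k=k, query_len=query.length, fwd=fwd, rev=rev, codes=codes)


# ---------------------------------------------------------------------------
# x-drop gapped extension

# backpointer bit layout per cell: bits 0-1 H source (0 diag, 1 E, 2 F,
# 3 path start), bit 2 E source (0 from H, 1 from E), bit 3 F source
# (0 from H, 1 from F)


def _xdrop_dir(a: bytes, b: bytes, scoring: ScoringScheme, x_drop: int):
    """Best-scoring alignment of prefixes of a and b whose path starts at
    (0,0), under x-drop pruning on H. Returns (score, a_used, b_used, ops)
    with ops in {'M','I','D'}: I consumes b only (gap in a), D consumes a
    only (gap in b)."""
    m, n = len(a), len(b)
    ge = scoring.gap_extend
    oe = scoring.gap_open + ge
    mt, mm = scoring.match, scoring.mismatch
    N = 0x4E  # 'N'

    best, bi, bj = 0, 0, 0
    # row 0: gaps in a only
    H_prev: list[int] = [0]
    E_prev: list[int] = [_NEG]
    F_prev: list[int] = [_NEG]
    ptr_rows: list[tuple[int, list[int]]] = []
    row0_ptr = [3]
    j = 1
    while j <= n:
        val = -(scoring.gap_open + j * ge)
        if val < best - x_drop:
            break
        H_prev.append(val)
        E_prev.append(val)
        F_prev.append(_NEG)
        row0_ptr.append(1 | (0 if j == 1 else 4))  # H from E; E from H at j=1
        j += 1
    ptr_rows.append((0, row0_ptr))
    lo_prev, hi_prev = 0, len(H_prev) - 1

    for i in range(1, m + 1):
        ca = a[i - 1]
        lo = lo_prev
        # dead columns at the left edge of the previous row can only seed F;
        # start the row at lo_prev (column lo-1 of this row is out of window).
        H_cur: list[int] = []
        E_cur: list[int] = []
        F_cur: list[int] = []
        ptr_cur: list[int] = []
        cutoff = best - x_drop
        row_best = _NEG
        j = lo
        hi_limit = min(n, hi_prev + 1 + x_drop // ge + 1)
        while j <= hi_limit:
            idx_prev = j - lo_prev
            # F: from row i-1, same column
            if 0 <= idx_prev <= hi_prev - lo_prev:
                h_up = H_prev[idx_prev]
                f_up = F_prev[idx_prev]
            else:
                h_up = f_up = _NEG
            f_from_h = h_up - oe
            f_from_f = f_up - ge
            if f_from_h >= f_from_f:
                f_val, f_src = f_from_h, 0
            else:
                f_val, f_src = f_from_f, 8
            # E: from this row, previous column
            if j - 1 >= lo and (j - 1 - lo) < len(H_cur):
                h_left = H_cur[j - 1 - lo]
                e_left = E_cur[j - 1 - lo]
            else:
                h_left = e_left = _NEG
            e_from_h = h_left - oe
            e_from_e = e_left - ge
            if e_from_h >= e_from_e:
                e_val, e_src = e_from_h, 0
            else:
                e_val, e_src = e_from_e, 4
            # diag
            idx_diag = j - 1 - lo_prev
            if j >= 1 and 0 <= idx_diag <= hi_prev - lo_prev:
                cb = b[j - 1]
                s = mt if (ca == cb and ca != N) else mm
                d_val = H_prev[idx_diag] + s
            else:
                d_val = _NEG
            # H = max(diag, E, F); no free restart away from the anchor
            h_val, h_src = d_val, 0
            if e_val > h_val:
                h_val, h_src = e_val, 1
            if f_val > h_val:
                h_val, h_src = f_val, 2
            if h_val < cutoff:
                h_val = e_val = f_val = _NEG
            H_cur.append(h_val)
            E_cur.append(e_val)
            F_cur.append(f_val)
            ptr_cur.append(h_src | e_src | f_src)
            if h_val > row_best:
                row_best = h_val
            if h_val > best:
                best, bi, bj = h_val, i, j
                cutoff = best - x_drop
            # stop extending right once past previous row's reach and dead
            if j > hi_prev and h_val <= _NEG and e_val <= _NEG:
                break
            j += 1
        # trim dead cells at both ends of the window
        left_trim = 0
        while left_trim < len(H_cur) and (
            H_cur[left_trim] <= _NEG
            and E_cur[left_trim] <= _NEG
            and F_cur[left_trim] <= _NEG
        ):
            left_trim += 1
        if left_trim == len(H_cur):
            break  # row fully dead: extension terminates
        right = len(H_cur)
        while right > left_trim and (
            H_cur[right - 1] <= _NEG
            and E_cur[right - 1] <= _NEG
            and F_cur[right - 1] <= _NEG
        ):
            right -= 1
        ptr_rows.append((lo, ptr_cur))
        lo_prev = lo + left_trim
        hi_prev = lo + right - 1
        H_prev = H_cur[left_trim:right]
        E_prev = E_cur[left_trim:right]
        F_prev = F_cur[left_trim:right]
        if i == m:
            break

    # traceback from (bi, bj)
    ops: list[str] = []
    i, j, state = bi, bj, "H"
    while not (i == 0 and j == 0):
        lo, ptrs = ptr_rows[i]
        code = ptrs[j - lo]
        if state == "H":
            src = code & 3
            if src == 0:
                ops.append("M")
                i -= 1
                j -= 1
            elif src == 1:
                state = "E"
            elif src == 2:
                state = "F"
            else:  # path start
                break
        elif state == "E":
            ops.append("I")
            state = "E" if (code & 4) else "H"
            j -= 1
            if state == "E" and j == 0:
                state = "H"
        else:  # F
            ops.append("D")
            state = "F" if (code & 8) else "H"
            i -= 1
            if state == "F" and i == 0:
                state = "H"
    ops.reverse()
    return best, bi, bj, ops


def _hit_from_extension(
    qseq: str,
    scaf: str,
    qp: int,
    sp: int,
    scoring: ScoringScheme,
    x_drop: int,
) -> tuple[int, int, int, int, int, list[str]]:
    """Extend left and right from anchor cell (qp, sp); returns
    (score, qs, qe, ss, se, ops) in the coordinates of (qseq, scaf)."""
    score_r, ar, br, ops_r = _xdrop_dir(
        qseq[qp:].encode("ascii"), scaf[sp:].encode("ascii"), scoring, x_drop
    )
    score_l, al, bl, ops_l = _xdrop_dir(
        qseq[:qp][::-1].encode("ascii"), scaf[:sp][::-1].encode("ascii"),
        scoring, x_drop,
    )
    ops = ops_l[::-1] + ops_r
    return score_l + score_r, qp - al, qp + ar, sp - bl, sp + br, ops


_GAP_RC = str.maketrans("ACGTN-", "TGCAN-")


def _rc_gapped(s: str) -> str:
    return s.translate(_GAP_RC)[::-1]


def _columns(qseq: str, scaf: str, qs: int, ss: int, ops: list[str]):
    """Walk ops; return (matches, gap_cols, subject_aln, match_cells)."""
    qi, si = qs, ss
    matches = 0
    gap_cols = 0
    sub_chars: list[str] = []
    cells: list[tuple[int, int]] = []
    for op in ops:
        if op == "M":
            cq, cs = qseq[qi], scaf[si]
            if cq == cs and cq != "N":
                matches += 1
            sub_chars.append(cs)
            cells.append((qi, si))
            qi += 1
            si += 1
        elif op == "I":
            sub_chars.append(scaf[si])
            si += 1
            gap_cols += 1
        else:  # D
            sub_chars.append("-")
            qi += 1
            gap_cols += 1
    return matches, gap_cols, "".join(sub_chars), cells


def extend_seed(
    scaffold_seq: str,
    query: QueryGene,
    seed_match: tuple[int, int, str],
    scoring: ScoringScheme | None = None,
    x_drop: int = 50,
    score_min: int = 0,
    scaffold_id: str = "scaffold",
    k: int = 11,
) -> AlignmentHit | None:
    """Gapped x-drop extension of one exact seed (scaffold_pos, query_pos,
    strand); query_pos is on the forward query for '+' and on the
    reverse-complemented query for '-'. Returns None below score_min."""
    scoring = scoring if scoring is not None else ScoringScheme()
    sp, qp, strand = seed_match
    qseq = query.sequence if strand == "+" else reverse_complement(query.sequence)
    score, qs, qe, ss, se, ops = _hit_from_extension(
        qseq, scaffold_seq, qp, sp, scoring, x_drop
    )
    if score < score_min or qe <= qs or se <= ss:
        return None
    matches, gap_cols, sub_aln, _ = _columns(qseq, scaffold_seq, qs, ss, ops)
    aln_len = len(ops)
    trace = "".join(ops)
    if strand == "-":
        Lq = query.length
        qs, qe = Lq - qe, Lq - qs
        trace = trace[::-1]
        sub_aln = _rc_gapped(sub_aln)
    return AlignmentHit(
        query_id=query.id, scaffold_id=scaffold_id,
        q_start=qs, q_end=qe, s_start=ss, s_end=se, strand=strand,
        aln_len=aln_len, identity=matches / aln_len, score=float(score),
        gaps=gap_cols, trace=trace, subject_aln=sub_aln,
    )


# ---------------------------------------------------------------------------
# full search


def _dedup_overlaps(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Per scaffold+strand, transitively group hits with overlapping scaffold
    intervals and keep the best of each group (highest score, then longest
    subject span, then leftmost)."""
    kept: list[AlignmentHit] = []
    by_group: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        by_group.setdefault((h.scaffold_id, h.strand), []).append(h)
    for group in by_group.values():
        group.sort(key=lambda h: (h.s_start, h.s_end))
        cluster: list[AlignmentHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.s_start >= cluster_end:
                kept.append(_best_of(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.s_end)
        if cluster:
            kept.append(_best_of(cluster))
    kept.sort(key=lambda h: (h.scaffold_id, h.s_start, h.s_end, h.strand))
    return kept


def _best_of(cluster: list[AlignmentHit]) -> AlignmentHit:
    return max(
        cluster,
        key=lambda h: (h.score, h.subject_span, -h.s_start, -h.q_start),
    )


def search(
    query: QueryGene,
    assembly: GenomeAssembly,
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """All local alignments of the query against every scaffold, both strands,
    above the score floor, deduplicated and sorted by (scaffold, start)."""
    params = params if params is not None else SearchParams()
    if len(assembly) == 0:
        raise ValueError("assembly has no scaffolds")
    if query.length < params.k:
        raise ValueError("query shorter than seed length")
    index = build_seed_index(query, params.k)
    k = params.k
    strand_seq = {"+": query.sequence, "-": reverse_complement(query.sequence)}
    hits: list[AlignmentHit] = []

    for sid in assembly.ids():
        scaf = assembly.sequence(sid)
        enc = _encode(scaf)
        codes, valid = _kmer_codes(enc, k)
        if codes.size == 0:
            continue
        mask = valid & np.isin(codes, index.codes)
        positions = np.nonzero(mask)[0]
        # match-path cells of accepted hits, per strand, in strand-local
        # query coordinates; seeds fully on a known path are redundant
        path_cells: dict[str, set[tuple[int, int]]] = {"+": set(), "-": set()}
        seeds: list[tuple[int, int, str]] = []
        for p in positions:
            c = int(codes[p])
            for qp in index.fwd.get(c, ()):
                seeds.append((int(p), int(qp), "+"))
            for qp in index.rev.get(c, ()):
                seeds.append((int(p), int(qp), "-"))
        seeds.sort(key=lambda t: (t[2], t[0] - t[1], t[0]))
        for sp, qp, strand in seeds:
            cells = path_cells[strand]
            if cells and all((qp + t, sp + t) in cells for t in range(k)):
                continue
            qseq = strand_seq[strand]
            score, qs, qe, ss, se, ops = _hit_from_extension(
                qseq, scaf, qp, sp, params.scoring, params.x_drop
            )
            if qe <= qs or se <= ss:
                continue
            matches, gap_cols, sub_aln, mcells = _columns(qseq, scaf, qs, ss, ops)
            cells.update(mcells)
            if score < params.score_min:
                continue
            aln_len = len(ops)
            trace = "".join(ops)
            if strand == "-":
                Lq = query.length
                fqs, fqe = Lq - qe, Lq - qs
                trace = trace[::-1]
                sub_aln = _rc_gapped(sub_aln)
            else:
                fqs, fqe = qs, qe
            hits.append(AlignmentHit(
                query_id=query.id, scaffold_id=sid,
                q_start=fqs, q_end=fqe, s_start=ss, s_end=se, strand=strand,
                aln_len=aln_len, identity=matches / aln_len,
                score=float(score), gaps=gap_cols,
                trace=trace, subject_aln=sub_aln,
            ))
    return _dedup_overlaps(hits)


# ---------------------------------------------------------------------------
# Smith-Waterman oracle (Gotoh three-matrix, exact)


def smith_waterman(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    max_cells: int = 10_000_000,
    max_tied_ends: int = 64,
) -> AlignmentHit:
    """Optimal local alignment of a (treated as query) vs b under affine gaps.

    Anti-diagonal vectorised DP over the Gotoh H/E/F matrices; ties among
    maximum-score end cells are broken by longest alignment, then leftmost
    start. Guarded to |a|*|b| <= max_cells.
    """
    scoring = scoring if scoring is not None else ScoringScheme()
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    if m * n > max_cells:
        raise ValueError(f"problem size {m}x{n} exceeds the {max_cells}-cell guard")
    ea, eb = _encode(a), _encode(b)
    ge = scoring.gap_extend
    oe = scoring.gap_open + ge

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    for d in range(2, m + n + 1):
        ilo = max(1, d - n)
        ihi = min(m, d - 1)
        if ilo > ihi:
            continue
        ii = np.arange(ilo, ihi + 1)
        jj = d - ii
        E[ii, jj] = np.maximum(H[ii, jj - 1] - oe, E[ii, jj - 1] - ge)
        F[ii, jj] = np.maximum(H[ii - 1, jj] - oe, F[ii - 1, jj] - ge)
        am = ea[ii - 1]
        bm = eb[jj - 1]
        s = np.where((am == bm) & (am < 4), scoring.match, scoring.mismatch)
        H[ii, jj] = np.maximum(
            np.maximum(H[ii - 1, jj - 1] + s, 0),
            np.maximum(E[ii, jj], F[ii, jj]),
        )

    best = int(H.max())
    if best == 0:  # no positive-scoring local alignment at all
        ends = np.array([[0, 0]])
    else:
        ends = np.argwhere(H == best)
    candidates = []
    for bi, bj in ends[:max_tied_ends]:
        ops, ai, aj = _sw_traceback(H, E, F, ea, eb, int(bi), int(bj), scoring)
        candidates.append((len(ops), -(ai + aj), ai, aj, ops, int(bi), int(bj)))
    length, _, ai, aj, ops, bi, bj = max(
        candidates, key=lambda t: (t[0], t[1], -t[2], -t[3])
    )
    matches, gap_cols, sub_aln, _ = _columns(a, b, ai, aj, ops)
    return AlignmentHit(
        query_id="a", scaffold_id="b",
        q_start=ai, q_end=bi, s_start=aj, s_end=bj, strand="+",
        aln_len=length, identity=matches / length if length else 0.0,
        score=float(best), gaps=gap_cols,
        trace="".join(ops), subject_aln=sub_aln,
    )


def _sw_traceback(H, E, F, ea, eb, i, j, scoring):
    ge = scoring.gap_extend
    oe = scoring.gap_open + ge
    ops: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = scoring.match if (ea[i - 1] == eb[j - 1] and ea[i - 1] < 4) else scoring.mismatch
            if h == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            ops.append("I")
            if E[i, j] == H[i, j - 1] - oe:
                state = "H"
            j -= 1
        else:  # F
            ops.append("D")
            if F[i, j] == H[i - 1, j] - oe:
                state = "H"
            i -= 1
    ops.reverse()
    return ops, i, j
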