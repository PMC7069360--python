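"""Synthetic genome assemblies with planted, ground-truthed NUMT insertions.

The generator builds multi-scaffold nuclear backgrounds and splices in mutated
copies of the mitochondrial query gene so that every detector branch is
exercised: interior insertions (detectable), insertions abutting a scaffold
edge, scaffolds that are nearly all mitochondrial (assembly contamination),
and sub-threshold fragments. Each plant is recorded in a TruthRecord so
precision and recall can be scored against known ground truth.

Sequence decay is modelled with a uniform (Jukes-Cantor-like) substitution
process plus short indels (length 1-3, geometric), matching the JC distance
used downstream so that divergence parameters are recoverable in a closed
loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import GenomeAssembly, QueryGene, reverse_complement, write_fasta

PLACEMENT_CLASSES = ("interior", "edge_start", "edge_end", "contamination")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion."""

    scaffold_id: str
    start: int
    end: int  # 0-based half-open on the emitted scaffold
    strand: str
    q_start: int
    q_end: int  # query fragment planted, 0-based half-open
    divergence: float
    indel_rate: float
    placement_class: str
    expected_detectable: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class InsertionSpec:
    """One requested plant: where it goes and how decayed it is."""

    placement_class: str
    frag_len_range: tuple[int, int]
    divergence: float = 0.0
    indel_rate: float = 0.0
    strand: str = "random"  # '+', '-', or 'random'

    def __post_init__(self) -> None:
        if self.placement_class not in PLACEMENT_CLASSES:
            raise ValueError(f"unknown placement class {self.placement_class!r}")
        if not 0 <= self.divergence < 0.75:
            raise ValueError("divergence must lie in [0, 0.75)")
        lo, hi = self.frag_len_range
        if not 1 <= lo <= hi:
            raise ValueError("bad fragment length range")


@dataclass
class SimConfig:
    n_scaffolds: int = 10
    scaffold_length_range: tuple[int, int] = (20_000, 60_000)
    gc: float = 0.40
    insertions: list[InsertionSpec] = field(default_factory=list)
    seed: int = 0
    min_len: int = 100  # detector length threshold used for expected_detectable
    contamination_span_frac: float = 0.97

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in the open interval (0, 1)")
        if self.n_scaffolds < 1:
            raise ValueError("need at least one scaffold")

    def to_dict(self) -> dict:
        return {
            "n_scaffolds": self.n_scaffolds,
            "scaffold_length_range": list(self.scaffold_length_range),
            "gc": self.gc,
            "seed": self.seed,
            "min_len": self.min_len,
            "contamination_span_frac": self.contamination_span_frac,
            "insertions": [
                {
                    "placement_class": ins.placement_class,
                    "frag_len_range": list(ins.frag_len_range),
                    "divergence": ins.divergence,
                    "indel_rate": ins.indel_rate,
                    "strand": ins.strand,
                }
                for ins in self.insertions
            ],
        }


def generate_background(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. nuclear background with P(G)+P(C) = gc."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in the open interval (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def random_query(length: int = 1534, gc: float = 0.38,
                 rng: np.random.Generator | None = None,
                 name: str = "cox1") -> QueryGene:
    """A synthetic AT-rich mitochondrial-gene stand-in (default length matches
    a typical decapod cox1 coding sequence)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return QueryGene(name, generate_background(length, gc, rng))


def mutate_fragment(
    fragment: str,
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Decay a fragment: per-site substitution at `divergence` to a uniformly
    chosen different base, then indels (length 1-3, geometric) at `indel_rate`
    per site. Returns (mutated sequence, realized substitutions, realized
    indel events)."""
    if not fragment:
        raise ValueError("fragment must be non-empty")
    if divergence >= 0.75:
        raise ValueError("divergence >= 0.75 is beyond JC identifiability")
    if divergence < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")

    arr = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i

    sub_mask = (rng.random(len(arr)) < divergence) & (codes < 4)
    n_sub = int(sub_mask.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub)
        codes[sub_mask] = (codes[sub_mask] + shift) % 4
        arr[sub_mask] = _BASES[codes[sub_mask]]
    seq = arr.tobytes().decode("ascii")

    n_indel = 0
    if indel_rate > 0:
        out: list[str] = []
        i = 0
        n = len(seq)
        while i < n:
            if rng.random() < indel_rate:
                n_indel += 1
                size = min(1 + rng.geometric(0.5) - 1, 3)
                if rng.random() < 0.5:  # insertion before this site
                    ins = _BASES[rng.integers(0, 4, size=size)].tobytes().decode()
                    out.append(ins)
                    out.append(seq[i])
                    i += 1
                else:  # deletion of up to `size` sites
                    i += size
            else:
                out.append(seq[i])
                i += 1
        seq = "".join(out)
        if not seq:  # pathological all-deleted case
            seq = fragment[0]
    return seq, n_sub, n_indel


def _pick_strand(policy: str, rng: np.random.Generator) -> str:
    if policy in "+-":
        return policy
    return "+" if rng.random() < 0.5 else "-"


def plant_numts(
    config: SimConfig,
    query: QueryGene,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeAssembly, list[TruthRecord]]:
    """Build the assembly: background scaffolds plus spliced-in mutated query
    fragments at positions dictated by each insertion's placement class.

    Contamination-class insertions each emit a dedicated scaffold in which the
    planted copy spans >= 95% of the scaffold. Planted insertions never
    overlap. ``expected_detectable`` is True only for interior plants whose
    mutated length meets the detector's minimum alignment length, so recall is
    scored over plants the filters are meant to keep.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo_len, hi_len = config.scaffold_length_range

    backgrounds = [
        generate_background(int(rng.integers(lo_len, hi_len + 1)), config.gc, rng)
        for _ in range(config.n_scaffolds)
    ]
    scaffold_ids = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]

    # plan: per background scaffold, list of (orig_pos, placed_seq, meta)
    plans: dict[int, list[tuple[int, str, dict]]] = {i: [] for i in range(config.n_scaffolds)}
    contam: list[tuple[str, dict]] = []

    normal = [s for s in config.insertions if s.placement_class != "contamination"]
    contam_specs = [s for s in config.insertions if s.placement_class == "contamination"]

    for idx, spec in enumerate(normal):
        flo, fhi = spec.frag_len_range
        flen = int(rng.integers(flo, min(fhi, query.length) + 1))
        qs = int(rng.integers(0, query.length - flen + 1))
        frag = query.sequence[qs:qs + flen]
        mutated, n_sub, n_ind = mutate_fragment(frag, spec.divergence, spec.indel_rate, rng)
        strand = _pick_strand(spec.strand, rng)
        placed = mutated if strand == "+" else reverse_complement(mutated)
        target = idx % config.n_scaffolds
        bg_len = len(backgrounds[target])
        if len(placed) > bg_len:
            raise ValueError(
                f"fragment of {len(placed)} bp does not fit scaffold of {bg_len} bp"
            )
        meta = {
            "q_start": qs, "q_end": qs + flen, "strand": strand,
            "divergence": spec.divergence, "indel_rate": spec.indel_rate,
            "placement_class": spec.placement_class,
        }
        if spec.placement_class == "edge_start":
            pos = 0
        elif spec.placement_class == "edge_end":
            pos = bg_len
        else:
            existing = plans[target]
            margin = 50
            for _attempt in range(200):
                pos = int(rng.integers(margin, bg_len - margin + 1))
                if all(abs(pos - p) > margin for p, _, _ in existing):
                    break
            else:
                raise ValueError("could not place non-overlapping insertion")
        plans[target].append((pos, placed, meta))

    for spec in contam_specs:
        flo, fhi = spec.frag_len_range
        flen = int(rng.integers(flo, min(fhi, query.length) + 1))
        qs = int(rng.integers(0, query.length - flen + 1))
        frag = query.sequence[qs:qs + flen]
        mutated, _, _ = mutate_fragment(frag, spec.divergence, spec.indel_rate, rng)
        strand = _pick_strand(spec.strand, rng)
        placed = mutated if strand == "+" else reverse_complement(mutated)
        contam.append((placed, {
            "q_start": qs, "q_end": qs + flen, "strand": strand,
            "divergence": spec.divergence, "indel_rate": spec.indel_rate,
            "placement_class": "contamination",
        }))

    scaffolds: dict[str, str] = {}
    truths: list[TruthRecord] = []
    for i, sid in enumerate(scaffold_ids):
        bg = backgrounds[i]
        inserts = sorted(plans[i], key=lambda t: t[0])
        pieces: list[str] = []
        cursor = 0
        shift = 0
        for pos, placed, meta in inserts:
            pieces.append(bg[cursor:pos])
            start = pos + shift
            pieces.append(placed)
            end = start + len(placed)
            truths.append(TruthRecord(
                scaffold_id=sid, start=start, end=end,
                strand=meta["strand"], q_start=meta["q_start"], q_end=meta["q_end"],
                divergence=meta["divergence"], indel_rate=meta["indel_rate"],
                placement_class=meta["placement_class"],
                expected_detectable=(
                    meta["placement_class"] == "interior"
                    and len(placed) >= config.min_len
                ),
            ))
            shift += len(placed)
            cursor = pos
        pieces.append(bg[cursor:])
        scaffolds[sid] = "".join(pieces)

    for j, (placed, meta) in enumerate(contam):
        sid = f"scaffold_mt_{j + 1}"
        total = max(int(round(len(placed) / config.contamination_span_frac)), len(placed))
        pad = total - len(placed)
        left = pad // 2
        right = pad - left
        seq = (
            (generate_background(left, config.gc, rng) if left else "")
            + placed
            + (generate_background(right, config.gc, rng) if right else "")
        )
        truths.append(TruthRecord(
            scaffold_id=sid, start=left, end=left + len(placed),
            strand=meta["strand"], q_start=meta["q_start"], q_end=meta["q_end"],
            divergence=meta["divergence"], indel_rate=meta["indel_rate"],
            placement_class="contamination", expected_detectable=False,
        ))
        scaffolds[sid] = seq

    assembly = GenomeAssembly(scaffolds)
    for t in truths:
        if t.end > assembly.length(t.scaffold_id):
            raise AssertionError("truth interval exceeds its scaffold")
    return assembly, truths


def plant_multispecies(
    query: QueryGene,
    n_species: int,
    per_species: int,
    interspecies_divergence: float,
    intraspecies_divergence: float,
    rng: np.random.Generator,
    interspecies_indel_rate: float = 0.0,
    intraspecies_indel_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Simulate NUMT sets from several species sharing one mitochondrial query.

    Each species gets an ancestral copy of the query mutated at the
    interspecies rate; its NUMTs are copies of that ancestor mutated at the
    intraspecies rate. Labels encode the species, so per-species monophyly of
    the resulting tree can be checked against truth.
    """
    if interspecies_divergence <= intraspecies_divergence:
        raise ValueError("interspecies divergence must exceed intraspecies divergence")
    sequences: list[tuple[str, str]] = []
    species_of: dict[str, str] = {}
    for s in range(n_species):
        species = f"sp{s + 1}"
        ancestor, _, _ = mutate_fragment(
            query.sequence, interspecies_divergence, interspecies_indel_rate, rng
        )
        for n in range(per_species):
            numt, _, _ = mutate_fragment(
                ancestor, intraspecies_divergence, intraspecies_indel_rate, rng
            )
            label = f"{species}_numt{n + 1}"
            sequences.append((label, numt))
            species_of[label] = species
    return sequences, species_of


# ---------------------------------------------------------------------------
# artifact writers


def write_truth(truths: Sequence[TruthRecord], bed_path: str | Path,
                tsv_path: str | Path) -> None:
    """Truth table as BED6 plus an extended TSV with simulation annotations."""
    import pandas as pd

    with open(bed_path, "w") as handle:
        for i, t in enumerate(truths):
            handle.write(
                f"{t.scaffold_id}\t{t.start}\t{t.end}\tplant_{i + 1}\t0\t{t.strand}\n"
            )
    rows = [
        {
            "scaffold_id": t.scaffold_id, "start": t.start, "end": t.end,
            "strand": t.strand, "q_start": t.q_start, "q_end": t.q_end,
            "divergence": t.divergence, "indel_rate": t.indel_rate,
            "placement_class": t.placement_class,
            "expected_detectable": t.expected_detectable,
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            scaffold_id=str(r.scaffold_id), start=int(r.start), end=int(r.end),
            strand=str(r.strand), q_start=int(r.q_start), q_end=int(r.q_end),
            divergence=float(r.divergence), indel_rate=float(r.indel_rate),
            placement_class=str(r.placement_class),
            expected_detectable=bool(r.expected_detectable),
        )
        for r in df.itertuples()
    ]


def write_sim_outputs(
    assembly: GenomeAssembly,
    truths: Sequence[TruthRecord],
    config: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assembly": outdir / "assembly.fasta",
        "truth_bed": outdir / "truth.bed",
        "truth_tsv": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_fasta(assembly.scaffolds.items(), paths["assembly"])
    write_truth(truths, paths["truth_bed"], paths["truth_tsv"])
    with open(paths["config"], "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)
    return paths
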