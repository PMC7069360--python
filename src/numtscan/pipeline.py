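"""End-to-end runs: scan a genome for NUMTs, write artifacts, score results.

``run_scan`` chains search (or BLAST-tabular ingestion) -> filters -> site
merging -> sequence extraction -> optional tree, and writes machine-readable
outputs (hits TSV + outfmt-6, filter report, BED, FASTA, Newick, JSON
summary). ``run_evaluate`` scores predicted insertion sites against a
simulation truth table at 50% reciprocal overlap.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .call import (FilterParams, count_sites, extract_numt_sequences,
                   filter_hits, merge_insertion_sites)
from .io import (BedRecord, GenomeAssembly, QueryGene, load_assembly,
                 load_query, read_bed, read_blast_tab, write_bed,
                 write_blast_tab, write_fasta, write_hits_tsv, write_newick)
from .phylo import (InsufficientOverlapError, induce_reference_msa,
                    jc_distance, nj_tree)
from .search import SearchParams, search
from .simulate import TruthRecord, read_truth_tsv

logger = logging.getLogger("numtscan")


@dataclass
class RunConfig:
    genome: str | Path
    query: str | Path
    outdir: str | Path
    blast_tab: str | Path | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    search_params: SearchParams = field(default_factory=SearchParams)
    min_shared_sites: int = 100
    build_tree: bool = True
    seed: int = 0

    def echo(self) -> dict:
        return {
            "genome": str(self.genome),
            "query": str(self.query),
            "blast_tab": str(self.blast_tab) if self.blast_tab else None,
            "outdir": str(self.outdir),
            "min_len": self.filter_params.min_len,
            "max_span_frac": self.filter_params.max_span_frac,
            "edge_tol": self.filter_params.edge_tol,
            "merge_gap": self.filter_params.merge_gap,
            "k": self.search_params.k,
            "x_drop": self.search_params.x_drop,
            "score_min": self.search_params.score_min,
            "min_shared_sites": self.min_shared_sites,
            "build_tree": self.build_tree,
            "seed": self.seed,
        }


def run_scan(config: RunConfig) -> dict:
    """Execute the full detection pipeline; returns the run summary dict
    (also written to summary.json). Zero hits is a successful outcome."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assembly = load_assembly(config.genome)
    query = load_query(config.query)
    logger.info(
        "loaded %d scaffolds (%d bp) and query %s (%d bp)",
        len(assembly), assembly.total_length, query.id, query.length,
    )

    if config.blast_tab is not None:
        hits = read_blast_tab(config.blast_tab, assembly, query)
        logger.info("ingested %d hits from %s", len(hits), config.blast_tab)
    else:
        hits = search(query, assembly, config.search_params)
        logger.info("search found %d hits", len(hits))

    report = filter_hits(hits, assembly, config.filter_params)
    loci = merge_insertion_sites(report.kept_hits, config.filter_params)
    sequences = extract_numt_sequences(assembly, loci)
    counts = count_sites(loci)
    logger.info(
        "filters kept %d/%d hits -> %d insertion sites",
        report.tallies["kept"], report.tallies["input"], counts["total"],
    )

    write_hits_tsv(hits, outdir / "hits.tsv")
    write_blast_tab(hits, outdir / "hits.outfmt6.tsv")
    report.to_tsv(outdir / "filter_report.tsv")
    write_bed(loci, outdir / "numts.bed", assembly)
    write_fasta(sequences, outdir / "numts.fasta")

    tree_note = None
    if config.build_tree and len(loci) >= 2:
        try:
            msa = induce_reference_msa(loci, query, assembly)
            msa.to_fasta(outdir / "numts_msa.fasta")
            dm = jc_distance(msa, min_shared_sites=config.min_shared_sites)
            tree = nj_tree(dm)
            write_newick(tree, outdir / "numts.nwk")
            tree_note = f"tree over {len(tree.leaves())} loci"
        except InsufficientOverlapError as exc:
            tree_note = f"tree skipped: {exc}"
            logger.warning("%s", tree_note)
    elif config.build_tree:
        tree_note = "tree skipped: fewer than 2 insertion sites"

    summary = {
        "tool": "numtscan",
        "version": __version__,
        "params": config.echo(),
        "n_hits_input": report.tallies["input"],
        "n_hits_kept": report.tallies["kept"],
        "n_hits_removed": report.tallies["removed"],
        "removed_by_reason": {
            reason: report.tallies[reason]
            for reason in ("min_length", "scaffold_span", "edge")
        },
        "insertion_sites": counts["total"],
        "per_scaffold": counts["per_scaffold"],
        "tree": tree_note,
        "elapsed_seconds": round(time.monotonic() - t0, 3),
    }
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary


# ---------------------------------------------------------------------------
# evaluation against simulation truth


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def evaluate_predictions(
    predictions: Sequence[BedRecord],
    truths: Sequence[TruthRecord],
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Precision/recall of predicted insertion sites against planted truth.

    A prediction is a true positive iff it reciprocally overlaps any truth
    interval by >= the threshold. Recall is computed over the
    expected-detectable truth rows only; precision is None when there are no
    predictions.
    """
    detectable = [t for t in truths if t.expected_detectable]
    tp = 0
    matched_pred_per_truth: dict[int, int] = {}
    for pred in predictions:
        hit_any = False
        for idx, truth in enumerate(truths):
            if truth.scaffold_id != pred.chrom:
                continue
            ov = _reciprocal_overlap((pred.start, pred.end), (truth.start, truth.end))
            if ov >= min_reciprocal_overlap:
                hit_any = True
                matched_pred_per_truth[idx] = matched_pred_per_truth.get(idx, 0) + 1
        tp += hit_any
    recalled = 0
    for idx, truth in enumerate(truths):
        if truth.expected_detectable and matched_pred_per_truth.get(idx, 0) > 0:
            recalled += 1
    n_pred = len(predictions)
    n_det = len(detectable)
    return {
        "n_predictions": n_pred,
        "n_truth": len(truths),
        "n_truth_detectable": n_det,
        "true_positives": tp,
        "false_positives": n_pred - tp,
        "recalled_detectable": recalled,
        "precision": (tp / n_pred) if n_pred else None,
        "recall": (recalled / n_det) if n_det else None,
        "min_reciprocal_overlap": min_reciprocal_overlap,
    }


def run_evaluate(
    predicted_bed: str | Path,
    truth_tsv: str | Path,
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    predictions = read_bed(predicted_bed)
    truths = read_truth_tsv(truth_tsv)
    return evaluate_predictions(predictions, truths, min_reciprocal_overlap)
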