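"""The composite evaluation pipeline behind ``wga-eval evaluate``.

Given one or more predicted alignments and optionally a truth alignment,
produces per-prediction machine-readable reports (precision/recall/F when
truth is available; coverage, PSAR-precision and pseudo F-score always) plus
a cross-prediction Jaccard matrix with its UPGMA clustering.  Every random
operation records the seed it consumed, so reruns are reproducible.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from . import closure, comparator, coverage, phylo, psar, regional
from .annotations import AnnotationSet
from .maf import MafBlock, read_maf

logger = logging.getLogger(__name__)

__all__ = ["run_full_evaluation"]


def _load(maf) -> list[MafBlock]:
    return read_maf(maf) if isinstance(maf, str) else list(maf)


def _genomes(blocks: Sequence[MafBlock]) -> set[str]:
    out: set[str] = set()
    for b in blocks:
        out |= b.genomes()
    return out


def run_full_evaluation(
    pred_mafs: Mapping[str, object],
    truth_maf=None,
    reference: str | None = None,
    samples: int = 100_000,
    seed: int = 0,
    bed_sets: Mapping[str, AnnotationSet] | None = None,
    psar_params: psar.PairHmmParams | None = None,
    psar_samples: int = 100,
    region: regional.Region | None = None,
) -> dict:
    """Run the full evaluation over named predictions.

    Returns a JSON-serialisable report: one entry per prediction (comparison
    to truth when given, always coverage / duplicative coverage after
    closure / PSAR-style statistics when a reference and region are usable),
    plus the pairwise Jaccard matrix and UPGMA newick when two or more
    predictions are supplied.
    """
    preds = {name: _load(m) for name, m in pred_mafs.items()}
    if not preds:
        raise ValueError("need at least one prediction")
    truth = _load(truth_maf) if truth_maf is not None else None

    naming = {name: _genomes(blocks) for name, blocks in preds.items()}
    if truth is not None:
        naming["<truth>"] = _genomes(truth)
    universe = set.union(*naming.values())
    for name, genomes in naming.items():
        if not genomes:
            raise ValueError(f"{name}: empty alignment")
        if genomes != universe:
            diff = sorted(universe - genomes)
            logger.warning("%s lacks genomes %s", name, diff)

    report: dict = {"seed": seed, "samples": samples, "predictions": {}}
    for name, blocks in preds.items():
        entry: dict = {}
        if truth is not None:
            result = comparator.compare_stratified(
                blocks, truth, bed_sets or {}, s=samples, seed=seed
            )
            entry["vs_truth"] = result.to_dict()
        genomes = sorted(_genomes(blocks))
        if len(genomes) >= 2:
            entry["overall_coverage"] = coverage.overall_coverage(blocks)
            closed = closure.transitive_closure(blocks)
            entry["transitively_closed"] = closure.is_transitively_closed(blocks)
            _, dup = coverage.coverage_matrix(closed, duplicative=True)
            entry["mean_duplicative_coverage"] = float(
                np.mean([v for row in dup for v in row])
            )
        if reference is not None and reference in _genomes(blocks):
            region_blocks = (
                regional.extract_region(blocks, region) if region else blocks
            )
            if region_blocks:
                msa = psar.prepare_alignment(region_blocks, reference)
                scores = psar.psar_pair_scores(
                    msa, psar_params, n_samples=psar_samples, seed=seed
                )
                prec = psar.overall_psar_precision(scores, reference)
                cov = coverage.overall_coverage(region_blocks)
                entry["psar_precision"] = prec
                entry["pseudo_f"] = psar.pseudo_f(prec, cov)
                entry["psar_seed"] = seed
        report["predictions"][name] = entry

    names = sorted(preds)
    if len(names) >= 2:
        n = len(names)
        matrix = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = comparator.jaccard_distance(
                    preds[names[i]], preds[names[j]], s=samples, seed=seed
                )
                matrix[i, j] = matrix[j, i] = d
        report["jaccard"] = {
            "labels": names,
            "matrix": matrix.tolist(),
            "upgma_newick": phylo.write_newick(
                phylo.upgma(phylo.DistanceMatrix(names, matrix))
            ),
        }
    return report
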