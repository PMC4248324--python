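"""Sampled comparison of alignment relations: precision, recall, F, Jaccard.

Whole-genome alignment relations are too large to intersect exhaustively (the
mammal-scale case runs to billions of pairs), so precision and recall are
estimated by sampling.  The estimator is a two-pass scheme:

pass 1
    iterate the MAF and count the eligible pairs, ``m``;
pass 2
    iterate again; for each column holding ``k`` eligible pairs draw
    ``x ~ Binomial(k, s/m)`` and sample ``x`` distinct pair indices uniformly
    without replacement, mapping integers to pairs through the bijection in
    :mod:`wgaeval.relation`.

The expected number of draws is ``s``; each eligible pair occurrence is
sampled with equal probability without ever enumerating the relation.  In the
degenerate limit ``s >= m`` the probability clamps at 1 and every pair is
drawn exactly once, making the estimates exact.

Precision of a prediction A against a truth B is the fraction of A's sampled
pairs found in B's relation; recall is the same with the roles swapped; the
F-score is their harmonic mean.  The Jaccard distance between two relations is
estimated from the same two directed overlap fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import AnnotationSet
from .maf import MafBlock, Residue, read_maf
from .relation import (
    PairFilter,
    PairIndex,
    ResiduePair,
    build_pair_index,
    column_pair_count,
    count_pairs,
    inter_genome_only,
    iter_column_pairs,
    pair_from_index,
)

DEFAULT_SAMPLES = 10_000_000  # per direction

__all__ = [
    "ComparisonResult",
    "sample_pairs",
    "overlap_fraction",
    "f_score",
    "compare",
    "compare_stratified",
    "compare_by_species_pair",
    "jaccard_distance",
    "DEFAULT_SAMPLES",
]


@dataclass
class ComparisonResult:
    """Precision/recall/F estimates with sampling metadata.

    ``samples_drawn_a`` counts draws from the prediction (precision side),
    ``samples_drawn_b`` draws from the truth (recall side).  ``strata`` holds
    nested results keyed by annotation label; an empty stratum is represented
    by a result with ``is_empty=True``.
    """

    precision: float
    recall: float
    f_score: float
    samples_drawn_a: int = 0
    samples_drawn_b: int = 0
    se_precision: float = 0.0
    se_recall: float = 0.0
    is_empty: bool = False
    strata: dict[str, "ComparisonResult"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "samples_drawn_a": self.samples_drawn_a,
            "samples_drawn_b": self.samples_drawn_b,
            "se_precision": self.se_precision,
            "se_recall": self.se_recall,
        }
        if self.is_empty:
            out["empty"] = True
        if self.strata:
            out["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return out


_EMPTY = ComparisonResult(
    precision=float("nan"), recall=float("nan"), f_score=float("nan"), is_empty=True
)


def _materialise(maf) -> list[MafBlock]:
    if isinstance(maf, str):
        return read_maf(maf)
    return list(maf)


def f_score(p: float, r: float) -> float:
    """Balanced F-score: the harmonic mean of precision and recall."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError(f"precision/recall out of [0,1]: {p}, {r}")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def sample_pairs(
    blocks: Sequence[MafBlock],
    s: int,
    rng: np.random.Generator | int,
    pair_filter: PairFilter | None = None,
    m: int | None = None,
) -> list[ResiduePair]:
    """Draw ~s eligible pair occurrences from a MAF by binomial column sampling.

    ``m`` may be supplied if pass 1 has already been run; otherwise the blocks
    are traversed once to count.  With a fixed seed the sample is reproducible:
    the random stream is consumed in file order, one binomial draw per column
    with eligible pairs.
    """
    if s < 1:
        raise ValueError("sample size s must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if m is None:
        m = count_pairs(blocks, pair_filter)
    if m == 0:
        raise ValueError("empty relation: no eligible pairs to sample")
    p = min(1.0, s / m)
    sample: list[ResiduePair] = []
    for block in blocks:
        for col in range(block.ncols):
            if pair_filter is None:
                residues = None
                n = sum(1 for row in block.rows if row.text[col] != "-")
                k = column_pair_count(n)
            else:
                residues = [
                    pr
                    for pr in iter_column_pairs(
                        block.column_residues(col), pair_filter
                    )
                ]
                k = len(residues)
            if k == 0:
                continue
            x = int(rng.binomial(k, p))
            if x == 0:
                continue
            idxs = rng.choice(k, size=x, replace=False)
            if residues is None:
                col_res = block.column_residues(col)
                sample.extend(pair_from_index(col_res, int(i)) for i in idxs)
            else:
                sample.extend(residues[int(i)] for i in idxs)
    return sample


def overlap_fraction(
    sample: Sequence[ResiduePair], other_index: PairIndex
) -> tuple[float, float]:
    """Fraction of sampled pairs present in another relation, with binomial SE."""
    n = len(sample)
    if n == 0:
        raise ValueError("empty sample")
    hits = sum(1 for pair in sample if pair in other_index)
    f = hits / n
    se = math.sqrt(f * (1.0 - f) / n)
    return f, se


def compare(
    pred_maf,
    true_maf,
    s: int = DEFAULT_SAMPLES,
    seed: int = 0,
    pair_filter: PairFilter | None = None,
) -> ComparisonResult:
    """Estimate precision/recall/F of a predicted MAF against a truth MAF.

    Two independent seeded streams are used, one per sampling direction, so
    results are reproducible given ``(files, s, seed)``.
    """
    pred = _materialise(pred_maf)
    true = _materialise(true_maf)
    res = _compare_blocks(pred, true, s, seed, pair_filter)
    if res.is_empty:
        raise ValueError("empty relation under the given filter")
    return res


def _compare_blocks(
    pred: list[MafBlock],
    true: list[MafBlock],
    s: int,
    seed: int,
    pair_filter: PairFilter | None,
) -> ComparisonResult:
    m_pred = count_pairs(pred, pair_filter)
    m_true = count_pairs(true, pair_filter)
    if m_pred == 0 or m_true == 0:
        return _EMPTY
    true_index = build_pair_index(true, pair_filter)
    pred_index = build_pair_index(pred, pair_filter)
    rng_a = np.random.default_rng([seed, 0])
    rng_b = np.random.default_rng([seed, 1])
    sample_a = sample_pairs(pred, s, rng_a, pair_filter, m=m_pred)
    sample_b = sample_pairs(true, s, rng_b, pair_filter, m=m_true)
    precision, se_p = overlap_fraction(sample_a, true_index)
    recall, se_r = overlap_fraction(sample_b, pred_index)
    return ComparisonResult(
        precision=precision,
        recall=recall,
        f_score=f_score(precision, recall),
        samples_drawn_a=len(sample_a),
        samples_drawn_b=len(sample_b),
        se_precision=se_p,
        se_recall=se_r,
    )


def _and_filters(*filters: PairFilter | None) -> PairFilter | None:
    active = [f for f in filters if f is not None]
    if not active:
        return None
    if len(active) == 1:
        return active[0]

    def combined(a: Residue, b: Residue) -> bool:
        return all(f(a, b) for f in active)

    return combined


def compare_stratified(
    pred_maf,
    true_maf,
    bed_sets: Mapping[str, AnnotationSet],
    s: int = DEFAULT_SAMPLES,
    seed: int = 0,
    pair_filter: PairFilter | None = None,
    both_residues: bool = False,
) -> ComparisonResult:
    """Overall comparison plus one nested result per annotation stratum.

    A pair belongs to a stratum if at least one of its residues lies in the
    stratum's intervals (strict mode: both residues).  A stratum whose eligible
    relation is empty is recorded as empty, not treated as an error.
    """
    pred = _materialise(pred_maf)
    true = _materialise(true_maf)
    overall = _compare_blocks(pred, true, s, seed, pair_filter)
    if overall.is_empty:
        raise ValueError("empty relation under the given filter")
    for label, annot in bed_sets.items():
        if both_residues:
            def stratum_filter(a, b, _annot=annot):
                return _annot.contains(a) and _annot.contains(b)
        else:
            def stratum_filter(a, b, _annot=annot):
                return _annot.contains(a) or _annot.contains(b)
        combined = _and_filters(pair_filter, stratum_filter)
        overall.strata[label] = _compare_blocks(pred, true, s, seed, combined)
    return overall


def _present_genomes(blocks: Iterable[MafBlock]) -> set[str]:
    out: set[str] = set()
    for block in blocks:
        out |= block.genomes()
    return out


def compare_by_species_pair(
    pred_maf,
    true_maf,
    s: int = DEFAULT_SAMPLES,
    seed: int = 0,
    reference: str | None = None,
) -> dict:
    """Per-genome-pair comparison for stratification by phylogenetic distance.

    Returns a dict with one :class:`ComparisonResult` per unordered genome
    pair (inter-genome pairs of those two genomes only) under key ``"pairs"``,
    the aggregate over all inter-genome pairs under ``"all"``, and — when a
    reference genome is named — the aggregate over reference-containing pairs
    under ``"reference"``.
    """
    pred = _materialise(pred_maf)
    true = _materialise(true_maf)
    genomes = sorted(_present_genomes(pred) | _present_genomes(true))
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    if reference is not None and reference not in genomes:
        raise ValueError(f"reference genome {reference!r} not present")
    results: dict[tuple[str, str], ComparisonResult] = {}
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            def pair_filter(a, b, _ga=ga, _gb=gb):
                return {a.genome, b.genome} == {_ga, _gb}

            results[(ga, gb)] = _compare_blocks(pred, true, s, seed, pair_filter)
    out = {
        "pairs": results,
        "all": _compare_blocks(pred, true, s, seed, inter_genome_only),
    }
    if reference is not None:
        def ref_filter(a, b, _ref=reference):
            return a.genome != b.genome and _ref in (a.genome, b.genome)

        out["reference"] = _compare_blocks(pred, true, s, seed, ref_filter)
    return out


def jaccard_distance(
    maf_a,
    maf_b,
    s: int = DEFAULT_SAMPLES,
    seed: int = 0,
    pair_filter: PairFilter | None = None,
) -> float:
    """Estimated Jaccard distance (1 - Jaccard similarity) between two relations.

    The directed overlap fractions pA (A's sample found in B) and pB give an
    intersection estimate I = (pA*mA + pB*mB)/2; the distance is
    1 - I/(mA + mB - I), clamped to [0, 1].
    """
    a = _materialise(maf_a)
    b = _materialise(maf_b)
    m_a = count_pairs(a, pair_filter)
    m_b = count_pairs(b, pair_filter)
    if m_a == 0 or m_b == 0:
        raise ValueError("empty relation")
    index_a = build_pair_index(a, pair_filter)
    index_b = build_pair_index(b, pair_filter)
    p_a, _ = overlap_fraction(
        sample_pairs(a, s, np.random.default_rng([seed, 0]), pair_filter, m=m_a),
        index_b,
    )
    p_b, _ = overlap_fraction(
        sample_pairs(b, s, np.random.default_rng([seed, 1]), pair_filter, m=m_b),
        index_a,
    )
    intersection = (p_a * m_a + p_b * m_b) / 2.0
    union = m_a + m_b - intersection
    if union <= 0:
        return 0.0
    return min(1.0, max(0.0, 1.0 - intersection / union))
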