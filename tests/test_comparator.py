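import math
import random

import numpy as np
import pytest

import wgaeval as w
from wgaeval.maf import Residue

from conftest import random_maf


def _pair_row_blocks(pairs, src=200):
    """One 2-row block per pair: a MAF whose relation is exactly `pairs`."""
    blocks = []
    for a, b in pairs:
        blocks.append(
            w.MafBlock(
                rows=[
                    w.MafRow(f"{a.genome}.{a.chrom}", a.pos, 1, "+", src, "A"),
                    w.MafRow(f"{b.genome}.{b.chrom}", b.pos, 1, "+", src, "A"),
                ]
            )
        )
    return blocks


@pytest.mark.parametrize(
    "p,r,expected",
    [(0.5, 0.5, 0.5), (1.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.98, 0.96, 0.969897)],
)
def test_f_score(p, r, expected):
    assert w.f_score(p, r) == pytest.approx(expected, abs=1e-6)


def test_f_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        w.f_score(1.2, 0.5)


def test_overlap_fraction_binomial_se():
    pairs = [
        w.make_pair(Residue("a", "c", i), Residue("b", "c", i)) for i in range(10)
    ]
    index = w.PairIndex()
    for pair in pairs[:7]:
        index.add(pair)
    f, se = w.overlap_fraction(pairs, index)
    assert f == pytest.approx(0.7)
    assert se == pytest.approx(math.sqrt(0.21 / 10))
    with pytest.raises(ValueError):
        w.overlap_fraction([], index)


def test_full_sampling_draws_every_pair_once():
    rng = random.Random(2)
    blocks = random_maf(rng, n_blocks=4)
    m = w.count_pairs(blocks)
    sample = w.sample_pairs(blocks, s=m, rng=0)
    assert sorted(sample) == sorted(w.iter_pairs(blocks))


def test_sample_pairs_errors():
    blocks = random_maf(random.Random(0))
    with pytest.raises(ValueError):
        w.sample_pairs(blocks, s=0, rng=0)
    empty_rel = [w.MafBlock(rows=[w.MafRow("gA.c", 0, 3, "+", 10, "ACG")])]
    with pytest.raises(ValueError, match="empty relation"):
        w.sample_pairs(empty_rel, s=10, rng=0)


def test_sampling_is_deterministic_given_seed():
    blocks = random_maf(random.Random(9), n_blocks=4)
    s1 = w.sample_pairs(blocks, s=20, rng=42)
    s2 = w.sample_pairs(blocks, s=20, rng=42)
    assert s1 == s2
    assert w.compare(blocks, blocks, s=20, seed=7).to_dict() == w.compare(
        blocks, blocks, s=20, seed=7
    ).to_dict()


def test_compare_identity_is_perfect():
    blocks = random_maf(random.Random(4), n_blocks=3)
    res = w.compare(blocks, blocks, s=10**6, seed=1)
    assert (res.precision, res.recall, res.f_score) == (1.0, 1.0, 1.0)


def test_truth_superset_of_prediction(toy_truth):
    """Prediction = half of the truth blocks: precision exact 1, recall exact ratio."""
    truth = toy_truth.truth_maf
    pred = truth[: len(truth) // 2]
    m_pred = w.count_pairs(pred)
    m_true = w.count_pairs(truth)
    res = w.compare(pred, truth, s=max(m_pred, m_true), seed=3)
    assert res.precision == 1.0
    # full sampling makes recall the exact deduplicated ratio
    assert res.recall == pytest.approx(len(w.build_pair_index(pred)) / len(w.build_pair_index(truth)))


def test_compare_symmetry_under_full_sampling(toy_truth):
    truth = toy_truth.truth_maf
    pred = w.corrupt(toy_truth, 0.9, 0.8, seed=11)
    m = max(w.count_pairs(pred), w.count_pairs(truth))
    ab = w.compare(pred, truth, s=m, seed=1)
    ba = w.compare(truth, pred, s=m, seed=2)
    assert ab.precision == pytest.approx(ba.recall)
    assert ab.recall == pytest.approx(ba.precision)


def test_compare_recovers_dialled_corruption(toy_truth):
    res = w.compare(
        w.corrupt(toy_truth, 0.9, 0.8, seed=5),
        toy_truth.truth_maf,
        s=len(toy_truth.truth_pairs),
        seed=6,
    )
    n = len(toy_truth.truth_pairs)
    assert abs(res.precision - 0.9) <= 3 * math.sqrt(0.9 * 0.1 / n) + 2 / n
    assert abs(res.recall - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / n)


def test_monotonicity_of_corruption(toy_truth):
    """Lower dials never raise the estimated precision/recall (construction sweep)."""
    m = len(toy_truth.truth_pairs)
    high = w.compare(w.corrupt(toy_truth, 1.0, 0.9, seed=1), toy_truth.truth_maf, s=m, seed=1)
    low = w.compare(w.corrupt(toy_truth, 0.7, 0.6, seed=1), toy_truth.truth_maf, s=m, seed=1)
    assert low.precision < high.precision
    assert low.recall < high.recall


def test_jaccard_identity_disjoint_and_overlap():
    pairs_a = [
        w.make_pair(Residue("a", "c", i), Residue("b", "c", i)) for i in range(100)
    ]
    pairs_b = [
        w.make_pair(Residue("a", "c", i), Residue("b", "c", i))
        for i in range(50, 150)
    ]
    a = _pair_row_blocks(pairs_a)
    b = _pair_row_blocks(pairs_b)
    assert w.jaccard_distance(a, a, s=10**4, seed=0) == 0.0
    disjoint = _pair_row_blocks(
        [w.make_pair(Residue("a", "c", i), Residue("b", "c", i)) for i in range(150, 160)]
    )
    assert w.jaccard_distance(a, disjoint, s=10**4, seed=0) == 1.0
    # |A|=|B|=100, intersection 50: distance = 1 - 50/150, exact at full sampling
    assert w.jaccard_distance(a, b, s=10**4, seed=0) == pytest.approx(2 / 3)


def test_jaccard_symmetry(toy_truth):
    a = toy_truth.truth_maf
    b = w.corrupt(toy_truth, 0.8, 0.8, seed=3)
    m = len(toy_truth.truth_pairs)
    d1 = w.jaccard_distance(a, b, s=m * 2, seed=1)
    d2 = w.jaccard_distance(b, a, s=m * 2, seed=1)
    assert d1 == pytest.approx(d2, abs=1e-9)


def test_stratified_full_and_empty_strata(toy_truth):
    truth = toy_truth.truth_maf
    pred = w.corrupt(toy_truth, 0.9, 0.8, seed=2)
    m = len(toy_truth.truth_pairs)
    everything = w.AnnotationSet()
    for genome in toy_truth.sequences:
        everything.add(toy_truth.seq_name(genome), 0, len(toy_truth.sequences[genome]))
    nothing = w.AnnotationSet.from_intervals([])
    res = w.compare_stratified(
        pred, truth, {"all": everything, "none": nothing}, s=m, seed=4
    )
    assert res.strata["all"].precision == pytest.approx(res.precision)
    assert res.strata["all"].recall == pytest.approx(res.recall)
    assert res.strata["none"].is_empty


def test_stratified_matches_exhaustive_oracle(toy_truth):
    """Per-stratum P/R at full sampling equal exact set ratios on that stratum."""
    truth = toy_truth.truth_maf
    pred = w.corrupt(toy_truth, 0.85, 0.75, seed=8)
    bed_sets = {
        label: annot
        for label, annot in toy_truth.annotation_sets().items()
        if label in ("genic", "repetitive")
    }
    m = len(toy_truth.truth_pairs)
    res = w.compare_stratified(pred, truth, bed_sets, s=2 * m, seed=9)
    pred_rel = set(w.iter_pairs(pred))
    true_rel = set(w.iter_pairs(truth))
    for label, annot in bed_sets.items():
        in_stratum = lambda p: annot.contains(p[0]) or annot.contains(p[1])
        ps = {p for p in pred_rel if in_stratum(p)}
        ts = {p for p in true_rel if in_stratum(p)}
        assert res.strata[label].precision == pytest.approx(len(ps & ts) / len(ps))
        assert res.strata[label].recall == pytest.approx(len(ps & ts) / len(ts))


def test_by_species_pair(toy_truth):
    truth = toy_truth.truth_maf
    m = len(toy_truth.truth_pairs)
    out = w.compare_by_species_pair(truth, truth, s=m, seed=0, reference="A")
    for result in out["pairs"].values():
        assert result.precision == 1.0 and result.recall == 1.0
    assert set(out["pairs"]) == {("A", "B"), ("A", "C"), ("B", "C")}
    assert out["reference"].precision == 1.0
    with pytest.raises(ValueError, match="reference"):
        w.compare_by_species_pair(truth, truth, s=m, seed=0, reference="nope")


def test_two_genome_pair_equals_overall():
    gs = w.evolve("(A:0.05,B:0.05);", 400, w.EvolParams(indel_rate=0.02), seed=3)
    truth = gs.truth_maf
    pred = w.corrupt(gs, 0.9, 0.9, seed=1)
    m = len(gs.truth_pairs) * 2
    out = w.compare_by_species_pair(pred, truth, s=m, seed=5)
    only = out["pairs"][("A", "B")]
    overall = w.compare(pred, truth, s=m, seed=5, pair_filter=w.inter_genome_only)
    assert only.precision == pytest.approx(overall.precision)
    assert only.recall == pytest.approx(overall.recall)
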