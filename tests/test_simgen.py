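import math

import numpy as np
import pytest

import wgaeval as w


def test_null_evolution_gives_identical_leaves_and_perfect_self_score():
    gs = w.evolve(
        "((A:0.0,B:0.0):0.0,C:0.0);", 300, w.EvolParams(sub_rate=0, indel_rate=0), seed=1
    )
    assert len(set(gs.sequences.values())) == 1
    assert len(gs.truth_maf) == 1  # one gapless block over all leaves
    assert gs.truth_maf[0].ncols == 300
    assert len(gs.truth_pairs) == 300 * 3  # C(3,2) per column
    res = w.compare(gs.truth_maf, gs.truth_maf, s=10**6, seed=0)
    assert (res.precision, res.recall, res.f_score) == (1.0, 1.0, 1.0)


def test_no_duplication_means_zero_duplicative_coverage(toy_truth):
    for ga in "ABC":
        for gb in "ABC":
            if ga != gb:
                assert w.duplicative_coverage(toy_truth.truth_maf, ga, gb) == 0.0


def test_jukes_cantor_closed_form():
    """Observed mismatch fraction matches (3/4)(1 - exp(-4t/3)) at distance t."""
    t = 0.2
    gs = w.evolve(f"(X:{t / 2},Y:{t / 2});", 20_000, w.EvolParams(indel_rate=0), seed=6)
    diff = sum(
        1
        for a, b in gs.truth_pairs
        if gs.sequences[a.genome][a.pos] != gs.sequences[b.genome][b.pos]
    )
    n = len(gs.truth_pairs)
    expected = 0.75 * (1 - math.exp(-4 * t / 3))
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(diff / n - expected) <= 3 * se


def test_event_length_bookkeeping(toy_truth_events):
    for genome, s in toy_truth_events.stats.items():
        assert (
            s["length"]
            == toy_truth_events.root_length
            + s["insertions"]
            + s["duplicated"]
            - s["deletions"]
        ), genome


def test_truth_map_is_transitively_closed(toy_truth_events):
    assert w.is_transitively_closed(toy_truth_events.truth_maf)
    maf_relation = set(w.iter_pairs(toy_truth_events.truth_maf))
    assert maf_relation == toy_truth_events.truth_pairs


def test_annotations_cover_every_leaf_residue(toy_truth):
    for genome, per in toy_truth.annotations.items():
        covered = sum(end - start for ivals in per.values() for start, end in ivals)
        assert covered == len(toy_truth.sequences[genome])


def test_inversions_produce_minus_strand_truth_rows():
    gs = w.evolve(
        "(A:0.2,B:0.2);", 800, w.EvolParams(sub_rate=0.1, inv_rate=0.01), seed=8
    )
    strands = {r.strand for b in gs.truth_maf for r in b.rows}
    assert "-" in strands
    # relation is still orientation-free and self-consistent
    res = w.compare(gs.truth_maf, gs.truth_maf, s=10**6, seed=0)
    assert res.precision == 1.0


def test_corrupt_identity(toy_truth):
    pred = w.corrupt(toy_truth, 1.0, 1.0, seed=0)
    assert set(w.iter_pairs(pred)) == toy_truth.truth_pairs


def test_corrupt_perfect_precision_half_recall(toy_truth):
    pred = w.corrupt(toy_truth, 1.0, 0.5, seed=1)
    relation = set(w.iter_pairs(pred))
    assert relation <= toy_truth.truth_pairs  # precision exactly 1
    recall = len(relation) / len(toy_truth.truth_pairs)
    n = len(toy_truth.truth_pairs)
    assert abs(recall - 0.5) <= 3 * math.sqrt(0.25 / n)


def test_corrupt_dialled_grid_point(toy_truth):
    pred = w.corrupt(toy_truth, 0.9, 0.8, seed=2)
    relation = set(w.iter_pairs(pred))
    true_pos = relation & toy_truth.truth_pairs
    precision = len(true_pos) / len(relation)
    recall = len(true_pos) / len(toy_truth.truth_pairs)
    n = len(toy_truth.truth_pairs)
    assert abs(precision - 0.9) <= 3 * math.sqrt(0.9 * 0.1 / n) + 2 / n
    assert abs(recall - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / n)


def test_corrupt_rejects_bad_targets(toy_truth):
    with pytest.raises(ValueError):
        w.corrupt(toy_truth, 0.0, 0.5)
    with pytest.raises(ValueError):
        w.corrupt(toy_truth, 0.5, 1.5)


def test_corrupt_infeasible_precision_errors():
    gs = w.evolve("(A:0.01,B:0.01);", 30, w.EvolParams(indel_rate=0), seed=3)
    with pytest.raises(ValueError, match="infeasible"):
        w.corrupt(gs, 0.01, 1.0, seed=0)


def test_evolve_validates_inputs():
    with pytest.raises(ValueError):
        w.evolve("(A:0.1,B:0.1);", 0)
    with pytest.raises(ValueError):
        w.EvolParams(sub_rate=-1)
    with pytest.raises(ValueError):
        w.EvolParams(ann_fractions=(("genic", 0.5),))


def test_evolve_deterministic_given_seed():
    a = w.evolve("(A:0.1,B:0.1);", 200, seed=5)
    b = w.evolve("(A:0.1,B:0.1);", 200, seed=5)
    assert a.sequences == b.sequences
    assert a.truth_pairs == b.truth_pairs


def test_duplication_creates_intra_genome_truth_pairs():
    gs = w.evolve(
        "(A:0.1,B:0.1);", 500, w.EvolParams(sub_rate=0.1, dup_rate=0.01), seed=9
    )
    if any(s["duplicated"] > 0 for s in gs.stats.values()):
        intra = [p for p in gs.truth_pairs if p[0].genome == p[1].genome]
        assert intra
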