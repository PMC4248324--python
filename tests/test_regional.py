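import pytest

import wgaeval as w
from wgaeval.regional import Region


def test_sample_region_defaults_and_bounds():
    regions = w.sample_regions({"r.chr1": 1_000_000}, n=5, window=500_000, seed=3)
    assert len(regions) == 5
    for reg in regions:
        assert reg.length == 500_000
        assert 0 <= reg.start <= 499_999


def test_sample_regions_deterministic_and_chromosome_safe():
    sizes = {"r.chr1": 600_000, "r.chr2": 700_000}
    r1 = w.sample_regions(sizes, n=8, window=400_000, seed=9)
    r2 = w.sample_regions(sizes, n=8, window=400_000, seed=9)
    assert r1 == r2
    for reg in r1:
        assert reg.end <= sizes[reg.seq_name]


def test_sample_regions_rejects_short_genome():
    with pytest.raises(ValueError):
        w.sample_regions({"r.chr1": 1000}, window=2000)


def _toy_block():
    return w.MafBlock(
        rows=[
            w.MafRow("R.c", 10, 10, "+", 100, "ACGTACGTAC"),
            w.MafRow("B.c", 0, 8, "+", 100, "AC-GTA-CGT"),
        ]
    )


def test_extract_block_fully_inside_unchanged():
    sub = w.extract_region([_toy_block()], Region("R.c", 0, 100))
    assert len(sub) == 1
    assert sub[0].rows[0].text == "ACGTACGTAC"


def test_extract_trims_straddling_block():
    """Reference residues 10..19; window [10,15) keeps 5 columns, hand-counted."""
    sub = w.extract_region([_toy_block()], Region("R.c", 10, 15))
    assert len(sub) == 1
    ref, other = sub[0].rows
    assert ref.text == "ACGTA"
    assert (ref.start, ref.size) == (10, 5)
    assert other.text == "AC-GT"
    assert (other.start, other.size) == (0, 4)


def test_extract_drops_blocks_without_reference():
    other = w.MafBlock(
        rows=[
            w.MafRow("B.c", 20, 4, "+", 100, "ACGT"),
            w.MafRow("C.c", 20, 4, "+", 100, "ACGT"),
        ]
    )
    sub = w.extract_region([_toy_block(), other], Region("R.c", 0, 100))
    assert len(sub) == 1


def test_extract_requires_reference_sequence():
    with pytest.raises(ValueError, match="absent"):
        w.extract_region([_toy_block()], Region("Z.c", 0, 10))


def test_extraction_never_invents_pairs(toy_truth):
    region = Region("A.chr1", 50, 400)
    sub = w.extract_region(toy_truth.truth_maf, region)
    full = w.build_pair_index(toy_truth.truth_maf)
    assert all(p in full for p in w.iter_pairs(sub))


def test_500kb_window_gives_500_bins():
    region = Region("R.c", 0, 500_000)
    track = w.bin_scores([], region, bin_size=1_000, truth_region=[])
    assert len(track) == 500
    assert all(score is None for _, score in track)


def test_perfect_prediction_scores_one_in_every_nonempty_bin(toy_truth):
    region = Region("A.chr1", 0, 1_000)
    sub = w.extract_region(toy_truth.truth_maf, region)
    track = w.bin_scores(sub, region, bin_size=100, truth_region=sub)
    scores = [s for _, s in track if s is not None]
    assert scores and all(s == 1.0 for s in scores)


def test_bins_partition_reference_pairs(toy_truth):
    region = Region("A.chr1", 0, 1_200)
    sub = w.extract_region(toy_truth.truth_maf, region)
    ref_pairs = {
        p
        for p in w.iter_pairs(sub)
        if any(
            r.genome == "A" and r.chrom == "chr1" and region.start <= r.pos < region.end
            for r in p
        )
    }
    from wgaeval.regional import _ref_bin

    binned = set()
    for pair in ref_pairs:
        assert _ref_bin(pair, region, 100, "A", "chr1")
        binned.add(pair)
    assert binned == ref_pairs


def test_corruption_confined_to_one_bin_only_drops_that_bin(toy_truth):
    region = Region("A.chr1", 0, 1_000)
    truth_sub = w.extract_region(toy_truth.truth_maf, region)
    bad_bin = Region("A.chr1", 300, 400)
    pred_sub = []
    for block in truth_sub:
        ref = next(r for r in block.rows if r.genome == "A")
        positions = [ref.forward_position(i) for i in range(ref.size)]
        if all(bad_bin.start <= p < bad_bin.end for p in positions):
            continue  # delete this block: corruption confined to bin 3
        pred_sub.append(block)
    assert len(pred_sub) < len(truth_sub)
    truth_track = w.bin_scores(truth_sub, region, 100, truth_region=truth_sub)
    pred_track = w.bin_scores(pred_sub, region, 100, truth_region=truth_sub)
    changed = [
        i
        for i, ((_, a), (_, b)) in enumerate(zip(truth_track, pred_track))
        if a != b
    ]
    assert changed and all(300 <= i * 100 < 400 for i in changed)


def test_pseudo_f_mode_runs(toy_truth):
    region = Region("A.chr1", 0, 600)
    sub = w.extract_region(toy_truth.truth_maf, region)
    msa = w.prepare_alignment(sub, "A")
    scores = w.psar_pair_scores(msa, n_samples=50, seed=1)
    track = w.bin_scores(sub, region, 200, psar_scores=scores, mode="pseudo_f")
    vals = [s for _, s in track if s is not None]
    assert vals and all(0.0 <= v <= 1.0 for v in vals)


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        w.bin_scores([], Region("R.c", 0, 100), 10, mode="nope")
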