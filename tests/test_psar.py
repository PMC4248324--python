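import math

import numpy as np
import pytest

import wgaeval as w
from wgaeval.maf import Residue
from wgaeval.psar import (
    MsaMatrix,
    PairHmmParams,
    backward_matrix,
    forward_matrix,
    match_posterior,
    sample_alignment,
)


def enumerate_paths(seq, profile, p: PairHmmParams):
    """Independent oracle: every pair-HMM path with its probability.

    Explicit recursion over the 3-state topology (match M, gaps X/Y, no X<->Y
    transitions, start in M, no end penalty); returns (logprob, matches) per
    path.  Exponential, so only for tiny instances.
    """
    n, m = len(seq), len(profile)
    ld, le = math.log(p.gap_open), math.log(p.gap_extend)
    lmm, lgm = math.log(1 - 2 * p.gap_open), math.log(1 - p.gap_extend)
    lq = math.log(0.25)
    results = []

    def rec(i, j, state, logp, matches):
        if i == n and j == m:
            results.append((logp, frozenset(matches)))
        if i < n and j < m:
            tr = lmm if state == "M" else lgm
            e = math.log(sum(p.emit(seq[i], b) for b in profile[j]) / len(profile[j]))
            rec(i + 1, j + 1, "M", logp + tr + e, matches + [(i, j)])
        if i < n and state in "MX":
            rec(i + 1, j, "X", logp + (ld if state == "M" else le) + lq, matches)
        if j < m and state in "MY":
            rec(i, j + 1, "Y", logp + (ld if state == "M" else le) + lq, matches)

    rec(0, 0, "M", 0.0, [])
    return results


def exact_match_probs(seq, profile, p: PairHmmParams) -> np.ndarray:
    paths = enumerate_paths(seq, profile, p)
    total = sum(math.exp(lp) for lp, _ in paths)
    probs = np.zeros((len(seq), len(profile)))
    for lp, matches in paths:
        for i, j in matches:
            probs[i, j] += math.exp(lp) / total
    return probs


SEQ = list("ACGT")
PROFILE = [["A"], ["C", "C"], ["G"], ["T", "A"]]
PARAMS = PairHmmParams()


def test_forward_total_matches_path_enumeration():
    paths = enumerate_paths(SEQ, PROFILE, PARAMS)
    total = math.log(sum(math.exp(lp) for lp, _ in paths))
    state = forward_matrix(SEQ, PROFILE, PARAMS)
    assert state.loglik == pytest.approx(total, abs=1e-10)


def test_forward_backward_posterior_matches_enumeration():
    exact = exact_match_probs(SEQ, PROFILE, PARAMS)
    fb = match_posterior(SEQ, PROFILE, PARAMS)
    assert np.max(np.abs(fb - exact)) < 1e-10


def test_sampled_path_frequencies_match_enumeration():
    """Stochastic traceback draws each path with its forward contribution."""
    state = forward_matrix(SEQ, PROFILE, PARAMS)
    rng = np.random.default_rng(12345)
    n = 4000
    counts = np.zeros((len(SEQ), len(PROFILE)))
    for _ in range(n):
        for i, j in sample_alignment(state, rng):
            counts[i, j] += 1
    freq = counts / n
    exact = exact_match_probs(SEQ, PROFILE, PARAMS)
    se = np.sqrt(np.clip(exact * (1 - exact), 1e-12, None) / n)
    assert np.all(np.abs(freq - exact) <= 3 * se + 1e-9)


def test_empty_instance_has_single_empty_path():
    state = forward_matrix([], [], PARAMS)
    assert state.loglik == 0.0
    rng = np.random.default_rng(0)
    assert sample_alignment(state, rng) == frozenset()


def test_match_dominates_in_the_limiting_case():
    p = PairHmmParams(p_match_emit=0.99, gap_open=0.001, gap_extend=0.5)
    post = match_posterior(["A"], [["A"]], p)
    assert post[0, 0] > 0.99


def test_traceback_is_deterministic_given_seed():
    state = forward_matrix(SEQ, PROFILE, PARAMS)
    paths1 = [sample_alignment(state, np.random.default_rng(9)) for _ in range(20)]
    paths2 = [sample_alignment(state, np.random.default_rng(9)) for _ in range(20)]
    assert paths1 == paths2


def _two_row_msa(text_a: str, text_b: str) -> MsaMatrix:
    def residues(genome, text):
        out, i = [], 0
        for ch in text:
            if ch == "-":
                out.append(None)
            else:
                out.append(Residue(genome, "c", i))
                i += 1
        return out

    return MsaMatrix(
        genomes=["A", "B"],
        texts=[text_a, text_b],
        residues=[residues("A", text_a), residues("B", text_b)],
    )


def test_identical_rows_score_high():
    text = "ACGTACGTACGTACGT"
    msa = _two_row_msa(text, text)
    p = PairHmmParams(p_match_emit=0.99, gap_open=0.01)
    scores = w.psar_pair_scores(msa, p, n_samples=1000, seed=1)
    assert len(scores.scores) == len(text)
    assert all(v >= 0.95 for v in scores.scores.values())


def test_unrelated_rows_score_low():
    rng = np.random.default_rng(0)
    bases = "ACGT"
    a = "".join(bases[i] for i in rng.integers(0, 4, 30))
    b = "".join(bases[i] for i in rng.integers(0, 4, 30))
    scores = w.psar_pair_scores(_two_row_msa(a, b), n_samples=500, seed=2)
    assert np.mean(list(scores.scores.values())) < 0.5


def test_scores_keyed_by_aligned_pairs_and_in_unit_interval():
    msa = _two_row_msa("AC-GT", "ACTGT")
    scores = w.psar_pair_scores(msa, n_samples=200, seed=3)
    expected_keys = {pair for pair, _, _, _ in msa.aligned_pairs()}
    assert set(scores.scores) == expected_keys
    assert all(0.0 <= v <= 1.0 for v in scores.scores.values())


def test_scores_deterministic_given_seed():
    msa = _two_row_msa("ACGTAC", "ACGTAC")
    s1 = w.psar_pair_scores(msa, n_samples=100, seed=5).scores
    s2 = w.psar_pair_scores(msa, n_samples=100, seed=5).scores
    assert s1 == s2


def test_psar_precision_and_overall():
    msa = _two_row_msa("ACGT", "ACGT")
    scores = w.psar_pair_scores(msa, n_samples=100, seed=1)
    prec = w.psar_precision(scores, "A", "B")
    assert prec == pytest.approx(np.mean(list(scores.scores.values())))
    assert w.overall_psar_precision(scores, "A") == pytest.approx(prec)
    with pytest.raises(ValueError):
        w.psar_precision(scores, "A", "Z")
    with pytest.raises(ValueError):
        w.overall_psar_precision(scores, "Z")


@pytest.mark.parametrize(
    "p,c,expected", [(1.0, 1.0, 1.0), (0.98, 0.5, 0.662162), (0.7, 0.0, 0.0)]
)
def test_pseudo_f(p, c, expected):
    assert w.pseudo_f(p, c) == pytest.approx(expected, abs=1e-6)


def test_pseudo_f_rejects_out_of_range():
    with pytest.raises(ValueError):
        w.pseudo_f(1.5, 0.5)


def test_prepare_alignment_single_block_identity(toy_truth):
    block = toy_truth.truth_maf[0]
    msa = w.prepare_alignment([block], "A")
    assert msa.genomes[0] == "A"
    assert sorted(msa.genomes) == sorted(block.genomes())
    assert msa.ncols == block.ncols


def test_prepare_alignment_drops_smaller_duplicate_copy():
    rows = [
        w.MafRow("R.c", 0, 6, "+", 50, "ACGTAC"),
        w.MafRow("B.c", 0, 6, "+", 50, "ACGTAC"),
        w.MafRow("B.c", 20, 2, "+", 50, "AC----"),
    ]
    msa = w.prepare_alignment([w.MafBlock(rows=rows)], "R")
    b_row = msa.texts[msa.genomes.index("B")]
    assert b_row == "ACGTAC"  # the 6-residue copy wins


def test_prepare_alignment_requires_reference():
    block = w.MafBlock(
        rows=[
            w.MafRow("A.c", 0, 2, "+", 10, "AC"),
            w.MafRow("B.c", 0, 2, "+", 10, "AC"),
        ]
    )
    with pytest.raises(ValueError, match="reference"):
        w.prepare_alignment([block], "Z")
    with pytest.raises(ValueError):
        w.prepare_alignment([], "A")


def test_mean_score_decreases_with_divergence():
    """More substitution distance between two rows never raises the mean score."""
    means = []
    for t in (0.02, 0.4, 1.5):
        gs = w.evolve(
            f"(X:{t / 2},Y:{t / 2});", 120, w.EvolParams(indel_rate=0.0), seed=4
        )
        msa = w.prepare_alignment(gs.truth_maf, "X")
        scores = w.psar_pair_scores(msa, n_samples=150, seed=4)
        means.append(np.mean(list(scores.scores.values())))
    assert means[0] > means[1] > means[2] - 0.02
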