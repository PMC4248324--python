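"""PSAR-style truth-free reliability scoring of alignment columns.

The idea: remove one row of a multiple alignment, sample suboptimal
re-alignments of that row against the profile of the remaining rows from the
forward matrix of a pair-HMM, and ask how often each originally aligned
residue pair is reproduced.  Averaged over leave-one-out rounds for both
members of a pair, that frequency — the *PSAR pair score* — approximates the
posterior probability that the pair is correctly aligned, given the edit
landscape around it.  Averaging pair scores over a genome pair gives
*PSAR-precision*, a truth-free precision proxy; its harmonic mean with
coverage is the *pseudo F-score*, a truth-free analog of the F-score.

The pair-HMM is the standard 3-state (match M, insert X, insert Y) global
model with affine gaps; parameters are generic DNA-alignment settings, fully
configurable.  This is a PSAR-*style* scorer: it follows the published
scheme's structure but fixes its own documented parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .maf import GAP, MafBlock, Residue
from .relation import ResiduePair, make_pair

NEG_INF = float("-inf")

__all__ = [
    "PairHmmParams",
    "MsaMatrix",
    "PsarScores",
    "prepare_alignment",
    "forward_matrix",
    "backward_matrix",
    "match_posterior",
    "sample_alignment",
    "psar_pair_scores",
    "psar_precision",
    "overall_psar_precision",
    "pseudo_f",
]


@dataclass(frozen=True)
class PairHmmParams:
    """3-state pair-HMM parameterization.

    p_match_emit
        probability mass on emitting an identical base pair from the match
        state; the remaining mass is split evenly over the three mismatches.
    gap_open (delta)
        transition M -> X or M -> Y; requires 2*delta < 1.
    gap_extend (epsilon)
        transition X -> X (resp. Y -> Y); gap states return to M with 1-eps.
    """

    p_match_emit: float = 0.85
    gap_open: float = 0.02
    gap_extend: float = 0.7

    def __post_init__(self) -> None:
        for name in ("p_match_emit", "gap_open", "gap_extend"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0,1)")
        if 2 * self.gap_open >= 1.0:
            raise ValueError("gap_open too large: need 2*delta < 1")

    def emit(self, a: str, b: str) -> float:
        a, b = a.upper(), b.upper()
        if a == "N" or b == "N":
            return 0.25
        return self.p_match_emit if a == b else (1.0 - self.p_match_emit) / 3.0


_Q_GAP = 0.25  # background emission of a residue against a gap


def _profile_emission_matrix(
    seq: Sequence[str], profile: Sequence[Sequence[str]], params: PairHmmParams
) -> np.ndarray:
    """log E[i, j]: mean emission of seq residue i against profile column j."""
    out = np.empty((len(seq), len(profile)))
    for j, column in enumerate(profile):
        if not column:
            raise ValueError(f"profile column {j} has no residues")
        for i, a in enumerate(seq):
            out[i, j] = math.log(
                sum(params.emit(a, b) for b in column) / len(column)
            )
    return out


@dataclass
class ForwardState:
    """Forward DP matrices in log space plus the total log-likelihood."""

    log_m: np.ndarray  # (n+1, m+1)
    log_x: np.ndarray
    log_y: np.ndarray
    log_e: np.ndarray  # (n, m) emission matrix
    loglik: float
    params: PairHmmParams


def forward_matrix(
    seq: Sequence[str], profile: Sequence[Sequence[str]], params: PairHmmParams
) -> ForwardState:
    """Forward recursion of the 3-state pair-HMM against a column profile.

    Profile columns are summarised by the arithmetic mean of match-state
    emission probabilities over their non-gap residues.  The start is treated
    as the match state; no end-transition penalty is applied (it would be a
    constant).  Empty seq and empty profile is the trivial instance with
    log-likelihood 0.
    """
    if (len(seq) == 0) != (len(profile) == 0) and (len(seq) == 0 or len(profile) == 0):
        pass  # one-sided empty instances are legal: pure-gap paths remain
    n, m = len(seq), len(profile)
    log_e = (
        _profile_emission_matrix(seq, profile, params)
        if n and m
        else np.zeros((n, m))
    )
    delta, eps = params.gap_open, params.gap_extend
    l_d, l_e = math.log(delta), math.log(eps)
    l_mm = math.log(1.0 - 2.0 * delta)
    l_gm = math.log(1.0 - eps)
    l_q = math.log(_Q_GAP)

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if i > 0 and j > 0:
                M[i, j] = log_e[i - 1, j - 1] + _lse3(
                    M[i - 1, j - 1] + l_mm,
                    X[i - 1, j - 1] + l_gm,
                    Y[i - 1, j - 1] + l_gm,
                )
            if i > 0:
                X[i, j] = l_q + np.logaddexp(M[i - 1, j] + l_d, X[i - 1, j] + l_e)
            if j > 0:
                Y[i, j] = l_q + np.logaddexp(M[i, j - 1] + l_d, Y[i, j - 1] + l_e)
    loglik = _lse3(M[n, m], X[n, m], Y[n, m]) if (n or m) else 0.0
    return ForwardState(M, X, Y, log_e, loglik, params)


def _lse3(a: float, b: float, c: float) -> float:
    hi = max(a, b, c)
    if hi == NEG_INF:
        return NEG_INF
    return hi + math.log(
        math.exp(a - hi) + math.exp(b - hi) + math.exp(c - hi)
    )


def backward_matrix(state: ForwardState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward DP matrices matching :func:`forward_matrix`'s model."""
    n, m = state.log_e.shape
    p = state.params
    l_d, l_e = math.log(p.gap_open), math.log(p.gap_extend)
    l_mm = math.log(1.0 - 2.0 * p.gap_open)
    l_gm = math.log(1.0 - p.gap_extend)
    l_q = math.log(_Q_GAP)
    BM = np.full((n + 1, m + 1), NEG_INF)
    BX = np.full((n + 1, m + 1), NEG_INF)
    BY = np.full((n + 1, m + 1), NEG_INF)
    BM[n, m] = BX[n, m] = BY[n, m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            match_term = (
                state.log_e[i, j] + BM[i + 1, j + 1]
                if i < n and j < m
                else NEG_INF
            )
            x_term = l_q + BX[i + 1, j] if i < n else NEG_INF
            y_term = l_q + BY[i, j + 1] if j < m else NEG_INF
            BM[i, j] = _lse3(l_mm + match_term, l_d + x_term, l_d + y_term)
            BX[i, j] = np.logaddexp(l_gm + match_term, l_e + x_term)
            BY[i, j] = np.logaddexp(l_gm + match_term, l_e + y_term)
    return BM, BX, BY


def match_posterior(
    seq: Sequence[str], profile: Sequence[Sequence[str]], params: PairHmmParams
) -> np.ndarray:
    """Exact forward-backward posterior P(seq residue i aligned to column j)."""
    state = forward_matrix(seq, profile, params)
    BM, _, _ = backward_matrix(state)
    n, m = state.log_e.shape
    post = np.zeros((n, m))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            post[i - 1, j - 1] = math.exp(
                state.log_m[i, j] + BM[i, j] - state.loglik
            )
    return post


def sample_alignment(
    state: ForwardState, rng: np.random.Generator
) -> frozenset[tuple[int, int]]:
    """Stochastic traceback: one alignment path drawn with its posterior weight.

    Returns the set of (seq_pos, profile_col) matches of the sampled path.
    """
    n = state.log_m.shape[0] - 1
    m = state.log_m.shape[1] - 1
    p = state.params
    l_d, l_e = math.log(p.gap_open), math.log(p.gap_extend)
    l_mm = math.log(1.0 - 2.0 * p.gap_open)
    l_gm = math.log(1.0 - p.gap_extend)
    matches: list[tuple[int, int]] = []
    if n == 0 and m == 0:
        return frozenset()
    current = _choose(
        rng, [state.log_m[n, m], state.log_x[n, m], state.log_y[n, m]]
    )
    i, j = n, m
    while (i, j) != (0, 0) or current != 0:
        if current == 0:  # match state at (i, j)
            matches.append((i - 1, j - 1))
            weights = [
                state.log_m[i - 1, j - 1] + l_mm,
                state.log_x[i - 1, j - 1] + l_gm,
                state.log_y[i - 1, j - 1] + l_gm,
            ]
            current = _choose(rng, weights)
            i, j = i - 1, j - 1
        elif current == 1:  # X: seq residue i against a gap
            weights = [state.log_m[i - 1, j] + l_d, state.log_x[i - 1, j] + l_e, NEG_INF]
            current = _choose(rng, weights)
            i = i - 1
        else:  # Y: profile column j against a gap
            weights = [state.log_m[i, j - 1] + l_d, NEG_INF, state.log_y[i, j - 1] + l_e]
            current = _choose(rng, weights)
            j = j - 1
    return frozenset(matches)


def _choose(rng: np.random.Generator, log_weights: list[float]) -> int:
    hi = max(log_weights)
    if hi == NEG_INF:
        raise RuntimeError("no feasible predecessor state in traceback")
    w = np.exp(np.asarray(log_weights) - hi)
    w /= w.sum()
    return int(rng.choice(3, p=w))


@dataclass
class MsaMatrix:
    """A stitched one-row-per-genome alignment matrix with residue bookkeeping.

    ``texts[r][c]`` is the gapped character of genome ``genomes[r]`` in column
    ``c``; ``residues[r][c]`` the corresponding forward-strand residue, or
    None on a gap.
    """

    genomes: list[str]
    texts: list[str]
    residues: list[list[Residue | None]]

    @property
    def ncols(self) -> int:
        return len(self.texts[0]) if self.texts else 0

    def aligned_pairs(self) -> list[tuple[ResiduePair, int, int, int]]:
        """All aligned pairs as (pair, column, row_a, row_b)."""
        out = []
        for c in range(self.ncols):
            present = [
                (r, self.residues[r][c])
                for r in range(len(self.genomes))
                if self.residues[r][c] is not None
            ]
            for ai in range(len(present)):
                for bi in range(ai + 1, len(present)):
                    ra, a = present[ai]
                    rb, b = present[bi]
                    out.append((make_pair(a, b), c, ra, rb))
        return out


def prepare_alignment(region_blocks, reference: str) -> MsaMatrix:
    """Flatten a regional MAF into one global matrix, one row per genome.

    Within each block, a genome represented by several rows (duplications)
    keeps only the row sharing the most columns with the reference row; blocks
    are concatenated in order of reference position; rows are ordered
    reference first, then by decreasing residue count; columns left entirely
    gapped are dropped.  Residues discarded here have no defined score.
    """
    blocks = [b for b in region_blocks if reference in b.genomes()]
    if not blocks:
        raise ValueError(f"reference genome {reference!r} absent from region")

    def ref_start(block: MafBlock) -> int:
        row = next(r for r in block.rows if r.genome == reference)
        return min(row.forward_position(0), row.forward_position(row.size - 1))

    blocks.sort(key=ref_start)

    chosen: list[dict[str, tuple[str, list[Residue | None]]]] = []
    genomes_seen: dict[str, int] = {}
    for block in blocks:
        ref_rows = [r for r in block.rows if r.genome == reference]
        ref_row = max(ref_rows, key=lambda r: r.size)
        per_genome: dict[str, tuple[str, list[Residue | None]]] = {}
        for genome in block.genomes():
            rows = [r for r in block.rows if r.genome == genome]
            if genome == reference:
                best = ref_row
            elif len(rows) == 1:
                best = rows[0]
            else:
                def ref_overlap(r):
                    return sum(
                        1
                        for c in range(block.ncols)
                        if r.text[c] != GAP and ref_row.text[c] != GAP
                    )

                best = max(rows, key=ref_overlap)
            res_map = [best.residue_at_column(c) for c in range(block.ncols)]
            per_genome[genome] = (best.text, res_map)
            genomes_seen[genome] = genomes_seen.get(genome, 0) + best.size
        chosen.append(per_genome)

    order = sorted(
        genomes_seen,
        key=lambda g: (g != reference, -genomes_seen[g], g),
    )
    texts = {g: [] for g in order}
    residues: dict[str, list[Residue | None]] = {g: [] for g in order}
    for per_genome, block in zip(chosen, blocks):
        width = block.ncols
        for g in order:
            if g in per_genome:
                text, res_map = per_genome[g]
                texts[g].append(text)
                residues[g].extend(res_map)
            else:
                texts[g].append(GAP * width)
                residues[g].extend([None] * width)
    full_texts = [("".join(texts[g])) for g in order]
    full_res = [residues[g] for g in order]
    keep = [
        c
        for c in range(len(full_texts[0]))
        if any(t[c] != GAP for t in full_texts)
    ]
    full_texts = ["".join(t[c] for c in keep) for t in full_texts]
    full_res = [[r[c] for c in keep] for r in full_res]
    return MsaMatrix(genomes=list(order), texts=full_texts, residues=full_res)


@dataclass
class PsarScores:
    """Per-pair reliability scores plus the sampling metadata that made them."""

    scores: dict[ResiduePair, float]
    pair_genomes: dict[ResiduePair, tuple[str, str]]
    n_samples: int
    seed: int
    params: PairHmmParams = field(default_factory=PairHmmParams)


def psar_pair_scores(
    msa: MsaMatrix,
    params: PairHmmParams | None = None,
    n_samples: int = 100,
    seed: int = 0,
) -> PsarScores:
    """Leave-one-out sampled reliability score for every aligned pair.

    For each row in turn the row is removed, ``n_samples`` re-alignments of it
    against the profile of the remaining rows are drawn from the forward
    matrix, and each originally aligned pair (x in the removed row, y in a
    kept row) receives a vote: the fraction of samples in which x was matched
    back to y's column.  A pair's final score is the mean of the votes from
    its two rows' rounds.
    """
    if params is None:
        params = PairHmmParams()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(msa.genomes) < 2:
        raise ValueError("need at least two rows to score")
    nrows = len(msa.genomes)
    score_sum: dict[ResiduePair, float] = {}
    score_n: dict[ResiduePair, int] = {}
    pair_rows: dict[ResiduePair, tuple[str, str]] = {}
    aligned = msa.aligned_pairs()

    for r in range(nrows):
        seq_chars = [ch for ch in msa.texts[r] if ch != GAP]
        seq_col_of: dict[int, int] = {}  # original column -> seq index
        i = 0
        for c, ch in enumerate(msa.texts[r]):
            if ch != GAP:
                seq_col_of[c] = i
                i += 1
        profile_cols: list[list[str]] = []
        profile_idx_of: dict[int, int] = {}  # original column -> profile index
        for c in range(msa.ncols):
            column = [
                msa.texts[q][c]
                for q in range(nrows)
                if q != r and msa.texts[q][c] != GAP
            ]
            if column:
                profile_idx_of[c] = len(profile_cols)
                profile_cols.append(column)
        if not seq_chars or not profile_cols:
            continue
        state = forward_matrix(seq_chars, profile_cols, params)
        rng = np.random.default_rng([seed, r])
        counts: dict[tuple[int, int], int] = {}
        for _ in range(n_samples):
            for match in sample_alignment(state, rng):
                counts[match] = counts.get(match, 0) + 1
        for pair, c, ra, rb in aligned:
            if r not in (ra, rb):
                continue
            if c not in seq_col_of or c not in profile_idx_of:
                continue
            key = (seq_col_of[c], profile_idx_of[c])
            vote = counts.get(key, 0) / n_samples
            score_sum[pair] = score_sum.get(pair, 0.0) + vote
            score_n[pair] = score_n.get(pair, 0) + 1
            ga, gb = msa.genomes[ra], msa.genomes[rb]
            pair_rows[pair] = (ga, gb) if ga <= gb else (gb, ga)

    scores = {pair: score_sum[pair] / score_n[pair] for pair in score_sum}
    return PsarScores(
        scores=scores,
        pair_genomes=pair_rows,
        n_samples=n_samples,
        seed=seed,
        params=params,
    )


def psar_precision(scores: PsarScores, genome_a: str, genome_b: str) -> float:
    """Mean PSAR pair score over the aligned residues of one genome pair."""
    key = (genome_a, genome_b) if genome_a <= genome_b else (genome_b, genome_a)
    values = [
        s for pair, s in scores.scores.items() if scores.pair_genomes[pair] == key
    ]
    if not values:
        raise ValueError(f"no scored pairs between {genome_a!r} and {genome_b!r}")
    return sum(values) / len(values)


def overall_psar_precision(scores: PsarScores, reference: str) -> float:
    """Mean of per-genome-pair PSAR-precision over pairs including the reference."""
    pairs = {
        key for key in scores.pair_genomes.values() if reference in key
    }
    if not pairs:
        raise ValueError(f"reference {reference!r} has no scored genome pairs")
    return sum(psar_precision(scores, a, b) for a, b in pairs) / len(pairs)


def pseudo_f(psar_prec: float, coverage: float) -> float:
    """Pseudo F-score: harmonic mean of PSAR-precision and coverage."""
    if not (0.0 <= psar_prec <= 1.0 and 0.0 <= coverage <= 1.0):
        raise ValueError("inputs must lie in [0,1]")
    if psar_prec + coverage == 0.0:
        return 0.0
    return 2.0 * psar_prec * coverage / (psar_prec + coverage)
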