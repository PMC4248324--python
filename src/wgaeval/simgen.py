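"""Toy forward-time genome evolution with residue-level truth tracking.

Every evaluation metric in this package needs a data set whose true homology
is known.  This module evolves a root sequence down a phylogeny, applying
Jukes-Cantor substitutions, geometric-length indels, inversions and tandem
duplications, while tracking the ancestral origin of every residue.  Two leaf
residues are truly homologous exactly when they descend from the same single
residue that existed in a common ancestor (the root, or the insertion point
of a later insertion); homologies predating the root are excluded by
construction.  That descent relation is an equivalence relation, so the truth
map is transitively closed, and it is emitted both as a pair set and as a MAF
of maximal co-linear blocks.

A companion corruptor degrades the truth into a "predicted" alignment with
dial-in precision and recall, giving construction-guaranteed ground truth for
testing the comparator: true pairs are dropped independently (recall dial)
and false pairs are injected by shifting retained pairs onto unaligned
positions (precision dial).

Substitutions follow Jukes-Cantor with rate 1 per site per unit branch
length, so two leaves at path distance t differ at an aligned site with
probability (3/4)(1 - exp(-4t/3)) — a closed form the simulator is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .maf import MafBlock, MafRow, Residue
from .relation import ResiduePair, make_pair
from .annotations import AnnotationSet

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_CHROM = "chr1"

__all__ = ["EvolParams", "ToyGenomeSet", "evolve", "corrupt"]


@dataclass(frozen=True)
class EvolParams:
    """Event rates of the toy evolver, all per site per unit branch length.

    Substitutions are Jukes-Cantor (each event replaces the base by one of
    the other three uniformly); indel lengths are geometric with the given
    mean; inversions flip a contiguous segment (and its strand context);
    duplications copy a segment in tandem, both copies remaining homologous
    to the segment's ancestors and to each other.
    """

    sub_rate: float = 1.0
    indel_rate: float = 0.05
    indel_mean: float = 3.0
    inv_rate: float = 0.0
    inv_mean: float = 20.0
    dup_rate: float = 0.0
    dup_mean: float = 20.0
    # root annotation layout: label fractions and mean segment length
    ann_fractions: tuple[tuple[str, float], ...] = (
        ("genic", 0.3),
        ("neutral", 0.5),
        ("repetitive", 0.2),
    )
    ann_segment_mean: float = 200.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "inv_rate", "dup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("indel_mean", "inv_mean", "dup_mean", "ann_segment_mean"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        total = sum(f for _, f in self.ann_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("annotation fractions must sum to 1")


# One residue travelling through the simulation:
# (origin_id, base, orient, key) — base is the current forward-strand base,
# orient is +/-1 relative to the root, key orders origins along the root.
_Res = tuple[int, str, int, float]


@dataclass
class ToyGenomeSet:
    """Simulator output: leaf sequences plus the residue-level truth."""

    sequences: dict[str, str]
    truth_pairs: set[ResiduePair]
    truth_maf: list[MafBlock]
    annotations: dict[str, dict[str, list[tuple[int, int]]]]  # genome -> label -> intervals
    tree: dendropy.Tree
    params: EvolParams
    root_length: int
    seed: int
    stats: dict[str, dict[str, int]] = field(default_factory=dict)

    def seq_name(self, genome: str) -> str:
        return f"{genome}.{DEFAULT_CHROM}"

    def annotation_sets(self) -> dict[str, AnnotationSet]:
        """Per-label AnnotationSets spanning all genomes (for stratification)."""
        labels = {lab for per in self.annotations.values() for lab in per}
        out = {}
        for label in sorted(labels):
            annot = AnnotationSet()
            for genome, per in self.annotations.items():
                for start, end in per.get(label, []):
                    annot.add(self.seq_name(genome), start, end)
            out[label] = annot
        return out

    def write_fasta(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for genome in sorted(self.sequences):
                fh.write(f">{self.seq_name(genome)}\n")
                seq = self.sequences[genome]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def _geometric_length(rng: np.random.Generator, mean: float) -> int:
    # geometric on {1, 2, ...} with the requested mean
    return int(rng.geometric(1.0 / mean))


class _Lineage:
    __slots__ = ("seq", "ins", "dels", "dup")

    def __init__(self, seq: list[_Res], ins: int = 0, dels: int = 0, dup: int = 0):
        self.seq = seq
        self.ins = ins
        self.dels = dels
        self.dup = dup


def _evolve_branch(
    parent: _Lineage,
    t: float,
    params: EvolParams,
    rng: np.random.Generator,
    next_origin: list[int],
) -> _Lineage:
    seq = list(parent.seq)
    child = _Lineage(seq, parent.ins, parent.dels, parent.dup)
    L0 = len(seq)
    if t <= 0 or L0 == 0:
        return child
    events: list[str] = []
    events += ["sub"] * rng.poisson(params.sub_rate * t * L0)
    events += ["indel"] * rng.poisson(params.indel_rate * t * L0)
    events += ["inv"] * rng.poisson(params.inv_rate * t * L0)
    events += ["dup"] * rng.poisson(params.dup_rate * t * L0)
    rng.shuffle(events)
    for ev in events:
        L = len(seq)
        if L == 0:
            break
        if ev == "sub":
            p = int(rng.integers(L))
            oid, base, orient, key = seq[p]
            seq[p] = (oid, _OTHER[base][int(rng.integers(3))], orient, key)
        elif ev == "indel":
            length = _geometric_length(rng, params.indel_mean)
            if rng.random() < 0.5:  # insertion
                p = int(rng.integers(L + 1))
                lo = seq[p - 1][3] if p > 0 else seq[0][3] - 1.0
                hi = seq[p][3] if p < L else seq[-1][3] + 1.0
                lo, hi = min(lo, hi), max(lo, hi)
                new = []
                for k in range(length):
                    key = lo + (hi - lo) * (k + 1) / (length + 1)
                    base = _BASES[int(rng.integers(4))]
                    new.append((next_origin[0], base, 1, key))
                    next_origin[0] += 1
                seq[p:p] = new
                child.ins += length
            else:  # deletion
                p = int(rng.integers(L))
                length = min(length, L - p)
                del seq[p : p + length]
                child.dels += length
        elif ev == "inv":
            length = min(_geometric_length(rng, params.inv_mean), L)
            p = int(rng.integers(L - length + 1))
            segment = seq[p : p + length][::-1]
            seq[p : p + length] = [
                (oid, _COMPLEMENT[b], -orient, key) for oid, b, orient, key in segment
            ]
        else:  # tandem duplication
            length = min(_geometric_length(rng, params.dup_mean), L)
            p = int(rng.integers(L - length + 1))
            seq[p + length : p + length] = list(seq[p : p + length])
            child.dup += length
    return child


def _root_annotation(
    root_length: int, params: EvolParams, rng: np.random.Generator
) -> list[str]:
    labels = [lab for lab, _ in params.ann_fractions]
    probs = np.array([f for _, f in params.ann_fractions])
    out: list[str] = []
    while len(out) < root_length:
        lab = labels[int(rng.choice(len(labels), p=probs))]
        seg = _geometric_length(rng, params.ann_segment_mean)
        out.extend([lab] * seg)
    return out[:root_length]


def evolve(
    tree: dendropy.Tree | str,
    root_length: int,
    params: EvolParams | None = None,
    seed: int = 0,
) -> ToyGenomeSet:
    """Evolve a random root sequence down a phylogeny with truth tracking.

    Returns leaf FASTA sequences, the transitively closed truth pair set, the
    truth MAF (maximal co-linear blocks), per-genome annotation intervals
    (labels laid out on the root and propagated positionally to the leaves),
    and per-leaf event bookkeeping (leaf length must equal root length plus
    insertions plus duplicated length minus deletions).
    """
    if params is None:
        params = EvolParams()
    if isinstance(tree, str):
        from .phylo import parse_newick

        tree = parse_newick(tree)
    if root_length < 1 or root_length > 10**6:
        raise ValueError("root_length must be in [1, 1e6]")
    rng = np.random.default_rng(seed)
    root_seq: list[_Res] = [
        (i, _BASES[int(b)], 1, float(i))
        for i, b in enumerate(rng.integers(0, 4, size=root_length))
    ]
    next_origin = [root_length]
    leaves: dict[str, _Lineage] = {}

    def descend(node: dendropy.Node, lineage: _Lineage) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            sub = _evolve_branch(lineage, t, params, rng, next_origin)
            if child.is_leaf():
                leaves[child.taxon.label] = sub
            else:
                descend(child, sub)

    root = _Lineage(root_seq)
    if tree.seed_node.is_leaf():
        leaves[tree.seed_node.taxon.label] = root
    else:
        descend(tree.seed_node, root)

    # group leaf residues by ancestral origin
    classes: dict[int, list[tuple[str, int, int, str, float]]] = {}
    for genome in sorted(leaves):
        for pos, (oid, base, orient, key) in enumerate(leaves[genome].seq):
            classes.setdefault(oid, []).append((genome, pos, orient, base, key))

    truth_pairs: set[ResiduePair] = set()
    maf_classes = []
    origin_key: dict[int, float] = {}
    for oid, members in classes.items():
        if len(members) < 2:
            continue
        residues = [
            Residue(genome, DEFAULT_CHROM, pos) for genome, pos, _, _, _ in members
        ]
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                truth_pairs.add(make_pair(residues[i], residues[j]))
        maf_classes.append((oid, sorted(members)))
        origin_key[oid] = members[0][4]
    maf_classes.sort(key=lambda item: (origin_key[item[0]], item[0]))

    sequences = {
        genome: "".join(base for _, base, _, _ in lineage.seq)
        for genome, lineage in leaves.items()
    }
    truth_maf = _emit_truth_maf(maf_classes, sequences)

    root_labels = _root_annotation(root_length, params, rng)
    annotations: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for genome, lineage in leaves.items():
        per: dict[str, list[tuple[int, int]]] = {}
        prev_label, start = None, 0
        for pos, (_, _, _, key) in enumerate(lineage.seq):
            label = root_labels[min(max(int(key), 0), root_length - 1)]
            if label != prev_label:
                if prev_label is not None:
                    per.setdefault(prev_label, []).append((start, pos))
                prev_label, start = label, pos
        if prev_label is not None:
            per.setdefault(prev_label, []).append((start, len(lineage.seq)))
        annotations[genome] = per

    stats = {
        genome: {
            "length": len(lineage.seq),
            "insertions": lineage.ins,
            "deletions": lineage.dels,
            "duplicated": lineage.dup,
        }
        for genome, lineage in leaves.items()
    }
    return ToyGenomeSet(
        sequences=sequences,
        truth_pairs=truth_pairs,
        truth_maf=truth_maf,
        annotations=annotations,
        tree=tree,
        params=params,
        root_length=root_length,
        seed=seed,
        stats=stats,
    )


def _emit_truth_maf(
    maf_classes: list[tuple[int, list[tuple[str, int, int, str, float]]]],
    sequences: dict[str, str],
) -> list[MafBlock]:
    """Chain co-linear truth columns into maximal gapless blocks."""
    blocks: list[MafBlock] = []
    run: list[list[tuple[str, int, int, str, float]]] = []

    def flush() -> None:
        if run:
            blocks.append(_run_to_block(run, sequences))

    for _, members in maf_classes:
        if run and _chains(run[-1], members):
            run.append(members)
        else:
            flush()
            run = [members]
    flush()
    return blocks


def _chains(prev, nxt) -> bool:
    if len(prev) != len(nxt):
        return False
    for (g1, p1, o1, _, _), (g2, p2, o2, _, _) in zip(prev, nxt):
        if g1 != g2 or o1 != o2 or p2 != p1 + o1:
            return False
    return True


def _run_to_block(run, sequences: dict[str, str]) -> MafBlock:
    width = len(run)
    rows = []
    for member in range(len(run[0])):
        genome, p0, orient, _, _ = run[0][member]
        src = len(sequences[genome])
        if orient == 1:
            start = p0
            text = sequences[genome][p0 : p0 + width]
            strand = "+"
        else:
            start = src - 1 - p0
            text = "".join(
                _COMPLEMENT[sequences[genome][p0 - i]] for i in range(width)
            )
            strand = "-"
        rows.append(
            MafRow(
                seq_name=f"{genome}.{DEFAULT_CHROM}",
                start=start,
                size=width,
                strand=strand,
                src_size=src,
                text=text,
            )
        )
    rows.sort(key=lambda r: (r.seq_name, r.start))
    return MafBlock(rows=rows)


def corrupt(
    truth: ToyGenomeSet,
    target_precision: float,
    target_recall: float,
    seed: int = 0,
    max_shift: int = 50,
) -> list[MafBlock]:
    """Degrade the truth into a prediction with dialled precision and recall.

    Each truth pair is retained independently with probability
    ``target_recall``; false pairs are then injected — one residue of a
    retained pair is offset by a random shift onto a position not aligned to
    the other residue — until retained/(retained+injected) meets
    ``target_precision`` up to rounding.  The relation is emitted as chained
    two-row blocks, so the output MAF's relation equals the constructed pair
    set exactly.
    """
    if not (0.0 < target_precision <= 1.0 and 0.0 < target_recall <= 1.0):
        raise ValueError("targets must lie in (0, 1]")
    pairs = sorted(truth.truth_pairs)
    if not pairs:
        raise ValueError("truth relation is empty")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) < target_recall
    retained = [pair for pair, k in zip(pairs, keep) if k]
    if not retained:
        raise ValueError("no pairs retained; recall target too low for this truth")
    n_inject = round(len(retained) * (1.0 / target_precision - 1.0))
    truth_set = truth.truth_pairs
    injected: set[ResiduePair] = set()
    attempts = 0
    limit = 200 * max(1, n_inject)
    lengths = {g: len(s) for g, s in truth.sequences.items()}
    while len(injected) < n_inject:
        attempts += 1
        if attempts > limit:
            raise ValueError(
                "could not inject enough false pairs; precision target infeasible"
            )
        a, b = retained[int(rng.integers(len(retained)))]
        if rng.random() < 0.5:
            a, b = b, a
        shift = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
        pos = b.pos + shift
        if not 0 <= pos < lengths[b.genome]:
            continue
        candidate_res = Residue(b.genome, b.chrom, pos)
        if candidate_res == a:
            continue
        candidate = make_pair(a, candidate_res)
        if candidate in truth_set or candidate in injected:
            continue
        injected.add(candidate)
    return _pairs_to_maf(retained + sorted(injected), truth.sequences)


def _pairs_to_maf(
    pairs: Iterable[ResiduePair], sequences: dict[str, str]
) -> list[MafBlock]:
    """Emit a pair set as 2-row MAF blocks, chaining co-linear runs."""
    ordered = sorted(
        set(pairs),
        key=lambda p: (p[0].genome, p[0].chrom, p[1].genome, p[1].chrom, p[0].pos, p[1].pos),
    )
    blocks: list[MafBlock] = []
    run_start: ResiduePair | None = None
    run_len = 0
    prev: ResiduePair | None = None

    def flush() -> None:
        if run_start is None:
            return
        a, b = run_start
        rows = []
        for res in (a, b):
            src = len(sequences[res.genome])
            rows.append(
                MafRow(
                    seq_name=f"{res.genome}.{res.chrom}",
                    start=res.pos,
                    size=run_len,
                    strand="+",
                    src_size=src,
                    text=sequences[res.genome][res.pos : res.pos + run_len],
                )
            )
        blocks.append(MafBlock(rows=rows))

    for pair in ordered:
        a, b = pair
        if (
            prev is not None
            and a.genome == prev[0].genome
            and a.chrom == prev[0].chrom
            and b.genome == prev[1].genome
            and b.chrom == prev[1].chrom
            and a.pos == prev[0].pos + 1
            and b.pos == prev[1].pos + 1
        ):
            run_len += 1
        else:
            flush()
            run_start, run_len = pair, 1
        prev = pair
    flush()
    return blocks
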