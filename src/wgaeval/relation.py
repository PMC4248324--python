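"""The alignment relation of a MAF: the set of unordered aligned residue pairs.

Every column of every block asserts homology among the residues it contains;
a column with n non-gap rows contributes n(n-1)/2 unordered pairs.  The union
of those pairs over the whole file is the *alignment relation*, the object all
accuracy metrics in this package are defined on.

Pairs are canonicalised (lexicographic order of ``(genome, chrom, pos)``) so
membership queries are orientation- and order-free, and a bijective index maps
integers in ``[0, n(n-1)/2)`` to the pairs of a column so they can be sampled
without being enumerated.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator

from .maf import MafBlock, Residue

PairFilter = Callable[[Residue, Residue], bool]

__all__ = [
    "ResiduePair",
    "make_pair",
    "column_residues",
    "column_pair_count",
    "pair_from_index",
    "iter_column_pairs",
    "iter_pairs",
    "count_pairs",
    "PairIndex",
    "build_pair_index",
    "inter_genome_only",
]

# A ResiduePair is a canonically ordered 2-tuple of Residues.
ResiduePair = tuple[Residue, Residue]


def make_pair(a: Residue, b: Residue) -> ResiduePair:
    """Canonical unordered pair: smaller residue first."""
    if a == b:
        raise ValueError(f"a residue cannot pair with itself: {a}")
    return (a, b) if a < b else (b, a)


def column_residues(block: MafBlock, col: int) -> list[Residue]:
    """Forward-strand residues of a column's non-gap rows, in row order."""
    return block.column_residues(col)


def column_pair_count(n: int) -> int:
    """Number of unordered pairs among n residues: n choose 2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def pair_from_index(residues: list[Residue], idx: int) -> ResiduePair:
    """Map an integer in [0, C(n,2)) to the idx-th unordered pair.

    Enumeration is row-major over index pairs (i, j) with i < j:
    (0,1), (0,2), ..., (0,n-1), (1,2), ...  This bijection lets a sampler
    draw pair identities from integers without materialising every pair.
    """
    n = len(residues)
    k = column_pair_count(n)
    if not 0 <= idx < k:
        raise IndexError(f"pair index {idx} out of range [0, {k})")
    i = 0
    remaining = idx
    while remaining >= n - 1 - i:
        remaining -= n - 1 - i
        i += 1
    j = i + 1 + remaining
    return make_pair(residues[i], residues[j])


def iter_column_pairs(
    residues: list[Residue], pair_filter: PairFilter | None = None
) -> Iterator[ResiduePair]:
    """All eligible unordered pairs of one column, in bijection order."""
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = residues[i], residues[j]
            if a == b:
                continue
            if pair_filter is None or pair_filter(a, b):
                yield make_pair(a, b)


def iter_pairs(
    blocks: Iterable[MafBlock], pair_filter: PairFilter | None = None
) -> Iterator[ResiduePair]:
    """Every eligible pair occurrence of a MAF, block by block, column by column.

    A pair appearing in several blocks is yielded once per occurrence;
    membership queries (see :class:`PairIndex`) use set semantics instead.
    """
    for block in blocks:
        for col in range(block.ncols):
            yield from iter_column_pairs(block.column_residues(col), pair_filter)


def count_pairs(
    blocks: Iterable[MafBlock], pair_filter: PairFilter | None = None
) -> int:
    """Pass-1 total of eligible pair occurrences (the sampler's ``m``)."""
    if pair_filter is None:
        total = 0
        for block in blocks:
            for col in range(block.ncols):
                n = sum(1 for row in block.rows if row.text[col] != "-")
                total += column_pair_count(n)
        return total
    return sum(1 for _ in iter_pairs(blocks, pair_filter))


def inter_genome_only(a: Residue, b: Residue) -> bool:
    """Filter excluding intra-genome (e.g. duplication) pairs."""
    return a.genome != b.genome


class PairIndex:
    """Constant-time membership structure over an alignment relation.

    Stores, per residue, the set of partner residues it is aligned to; queries
    are symmetric by construction and de-duplicated across blocks.
    """

    def __init__(self) -> None:
        self._partners: dict[Residue, set[Residue]] = {}
        self._n_pairs = 0

    def add(self, pair: ResiduePair) -> None:
        a, b = pair
        bucket = self._partners.setdefault(a, set())
        if b not in bucket:
            bucket.add(b)
            self._partners.setdefault(b, set()).add(a)
            self._n_pairs += 1

    def contains(self, pair: ResiduePair) -> bool:
        a, b = pair
        return b in self._partners.get(a, ())

    __contains__ = contains

    def partners(self, residue: Residue) -> frozenset[Residue]:
        return frozenset(self._partners.get(residue, ()))

    def residues(self) -> Iterator[Residue]:
        return iter(self._partners)

    def __len__(self) -> int:
        """Number of distinct pairs in the relation."""
        return self._n_pairs


def build_pair_index(
    blocks: Iterable[MafBlock], pair_filter: PairFilter | None = None
) -> PairIndex:
    """Index the (deduplicated) alignment relation of a MAF."""
    index = PairIndex()
    for pair in iter_pairs(blocks, pair_filter):
        index.add(pair)
    return index
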