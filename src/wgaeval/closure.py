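"""Transitive closure of a MAF's alignment relation.

Aligned-pair relations reported in MAF need not be transitive: a file may
align residue x to y in one block and y to z in another without ever aligning
x to z.  Under a strict homology interpretation that is inconsistent — if x
and y share an ancestor and y and z share an ancestor, then x and z do too.
The closure groups residues into equivalence classes with union-find over all
columns (near-linear in total residue occurrences) and re-emits each class of
two or more residues as an alignment column, merging runs of classes with
identical row composition and consecutive positions into maximal blocks.

The operation is relation-level only: merged columns are emitted on the '+'
strand at forward positions, original strand context and block scores are not
reconstructed, and no re-alignment is attempted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .maf import GAP, MafBlock, MafRow, Residue
from .relation import build_pair_index, column_pair_count

__all__ = ["transitive_closure", "is_transitively_closed"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self) -> None:
        self.parent: dict[Residue, Residue] = {}
        self.rank: dict[Residue, int] = {}

    def find(self, x: Residue) -> Residue:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def add(self, x: Residue) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.rank[x] = 0

    def union(self, x: Residue, y: Residue) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return
        if self.rank[rx] < self.rank[ry]:
            rx, ry = ry, rx
        self.parent[ry] = rx
        if self.rank[rx] == self.rank[ry]:
            self.rank[rx] += 1


def _forward_base(ch: str, strand: str) -> str:
    return ch if strand == "+" else ch.translate(_COMPLEMENT)


def _collect(blocks: Iterable[MafBlock]):
    """One sweep: union residues per column, remember base and srcSize."""
    uf = _UnionFind()
    bases: dict[Residue, str] = {}
    src_sizes: dict[tuple[str, str], int] = {}
    for block in blocks:
        per_row = [row.column_residue_indices() for row in block.rows]
        for row in block.rows:
            src_sizes[(row.genome, row.chrom)] = row.src_size
        for col in range(block.ncols):
            first: Residue | None = None
            for row, col_map in zip(block.rows, per_row):
                i = col_map[col]
                if i < 0:
                    continue
                res = Residue(row.genome, row.chrom, row.forward_position(i))
                uf.add(res)
                if res not in bases:
                    bases[res] = _forward_base(row.text[col], row.strand)
                if first is None:
                    first = res
                else:
                    uf.union(first, res)
    return uf, bases, src_sizes


def _classes(uf: _UnionFind) -> list[list[Residue]]:
    groups: dict[Residue, list[Residue]] = {}
    for res in uf.parent:
        groups.setdefault(uf.find(res), []).append(res)
    out = [sorted(g) for g in groups.values() if len(g) >= 2]
    out.sort(key=lambda g: g[0])
    return out


def transitive_closure(blocks) -> list[MafBlock]:
    """Return a MAF whose relation is the transitive closure of the input's.

    Each equivalence class of size >= 2 becomes one column; consecutive classes
    with identical (genome, chrom) composition whose member positions all
    advance by one are merged into a single gapless block.  Rows are ordered
    lexicographically by (genome, chrom, pos) of the block's first column.
    The result is itself transitively closed and idempotent under
    re-application.
    """
    blocks = list(blocks)
    uf, bases, src_sizes = _collect(blocks)
    classes = _classes(uf)
    out: list[MafBlock] = []
    run: list[list[Residue]] = []
    for cls in classes:
        if run and _extends(run[-1], cls):
            run.append(cls)
        else:
            if run:
                out.append(_emit(run, bases, src_sizes))
            run = [cls]
    if run:
        out.append(_emit(run, bases, src_sizes))
    return out


def _extends(prev: Sequence[Residue], nxt: Sequence[Residue]) -> bool:
    if len(prev) != len(nxt):
        return False
    for a, b in zip(prev, nxt):
        if a.genome != b.genome or a.chrom != b.chrom or b.pos != a.pos + 1:
            return False
    return True


def _emit(
    run: list[list[Residue]],
    bases: dict[Residue, str],
    src_sizes: dict[tuple[str, str], int],
) -> MafBlock:
    width = len(run)
    rows = []
    for member in range(len(run[0])):
        first = run[0][member]
        text = "".join(bases.get(cls[member], "N") for cls in run)
        name = f"{first.genome}.{first.chrom}" if first.chrom else first.genome
        rows.append(
            MafRow(
                seq_name=name,
                start=first.pos,
                size=width,
                strand="+",
                src_size=src_sizes[(first.genome, first.chrom)],
                text=text,
            )
        )
    return MafBlock(rows=rows)


def is_transitively_closed(blocks) -> bool:
    """True iff taking the transitive closure would leave the relation unchanged.

    Checked on class structure: the relation is closed exactly when it already
    contains every pair within each union-find class, i.e. when the number of
    distinct pairs equals the sum of C(|class|, 2).
    """
    blocks = list(blocks)
    uf, _, _ = _collect(blocks)
    expected = sum(column_pair_count(len(g)) for g in _classes(uf))
    return len(build_pair_index(blocks)) == expected
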