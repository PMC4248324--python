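"""BED annotation strata: per-genome interval sets used to subset metrics."""

from __future__ import annotations

from typing import IO, Iterable

from intervaltree import IntervalTree

from .maf import Residue, split_sequence_name

__all__ = ["AnnotationSet", "read_bed"]


class AnnotationSet:
    """Per-genome 0-based half-open intervals, queryable by residue.

    Sequence names may be either full MAF names (``genome.chrom``) or bare
    genome names; both address the same residue space.
    """

    def __init__(self) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    def add(self, seq_name: str, start: int, end: int) -> None:
        if end <= start:
            return
        genome, chrom = split_sequence_name(seq_name)
        self._trees.setdefault((genome, chrom), IntervalTree()).addi(start, end)

    def contains(self, residue: Residue) -> bool:
        tree = self._trees.get((residue.genome, residue.chrom))
        if tree is None and residue.chrom:
            # bare-genome BED entries apply to every chromosome of the genome
            tree = self._trees.get((residue.genome, ""))
        return bool(tree is not None and tree.overlaps_point(residue.pos))

    def is_empty(self) -> bool:
        return not self._trees

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]]
    ) -> "AnnotationSet":
        out = cls()
        for name, start, end in intervals:
            out.add(name, start, end)
        return out


def read_bed(source: str | IO[str]) -> AnnotationSet:
    """Read a BED3+ file (0-based half-open) into an :class:`AnnotationSet`."""
    if isinstance(source, str):
        handle: IO[str] = open(source, "rt", encoding="utf-8")
        own = True
    else:
        handle, own = source, False
    out = AnnotationSet()
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"BED line with <3 columns: {line!r}")
            out.add(fields[0], int(fields[1]), int(fields[2]))
    finally:
        if own:
            handle.close()
    return out
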