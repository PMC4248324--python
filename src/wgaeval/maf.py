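"""Reading, writing and coordinate arithmetic for MAF multiple alignments.

The MAF (UCSC multiple alignment format) stores an alignment as a series of
blocks; each block is a small gapped matrix whose rows carry strand-relative
coordinates.  All downstream metrics in this package work on *forward-strand
absolute positions*, so that the identity of an aligned residue pair does not
depend on the orientation in which an aligner chose to report it.  This module
owns the conversion.

Coordinates are 0-based throughout.  Row ``start`` is strand-relative, exactly
as printed in the file; :meth:`MafRow.forward_position` maps the i-th non-gap
residue of a row to its absolute position on the forward strand.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, NamedTuple

GAP = "-"
_ALLOWED_STRANDS = {"+", "-"}

__all__ = [
    "MafError",
    "MafParseError",
    "Residue",
    "MafRow",
    "MafBlock",
    "split_sequence_name",
    "parse_maf",
    "read_maf",
    "write_maf",
]


class MafError(ValueError):
    """An invariant of a MAF row or block is violated."""


class MafParseError(MafError):
    """A malformed line was encountered while parsing; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class Residue(NamedTuple):
    """One residue of one genome, addressed on the forward strand."""

    genome: str
    chrom: str
    pos: int


def split_sequence_name(name: str) -> tuple[str, str]:
    """Split a MAF sequence name into (genome, chrom) at the first dot.

    MAF producers conventionally name rows ``genome.chrom`` (e.g.
    ``dm3.chr3R``).  A name without a dot is treated as a bare genome with an
    empty chromosome field.
    """
    genome, _, chrom = name.partition(".")
    return genome, chrom


@dataclass
class MafRow:
    """One 's' line of a MAF block."""

    seq_name: str
    start: int  # strand-relative, 0-based
    size: int  # non-gap residue count
    strand: str  # '+' or '-'
    src_size: int  # length of the full source sequence
    text: str  # gapped sequence

    def __post_init__(self) -> None:
        self._col_to_residue_index: list[int] | None = None

    @property
    def genome(self) -> str:
        return split_sequence_name(self.seq_name)[0]

    @property
    def chrom(self) -> str:
        return split_sequence_name(self.seq_name)[1]

    def validate(self) -> None:
        if self.strand not in _ALLOWED_STRANDS:
            raise MafError(f"bad strand {self.strand!r} in row {self.seq_name}")
        if self.start < 0 or self.size < 0 or self.src_size <= 0:
            raise MafError(f"negative/zero coordinate field in row {self.seq_name}")
        non_gap = len(self.text) - self.text.count(GAP)
        if non_gap != self.size:
            raise MafError(
                f"row {self.seq_name}: size={self.size} but text has "
                f"{non_gap} non-gap characters"
            )
        if self.start + self.size > self.src_size:
            raise MafError(
                f"row {self.seq_name}: start+size={self.start + self.size} "
                f"exceeds srcSize={self.src_size}"
            )

    def forward_position(self, i: int) -> int:
        """Absolute forward-strand position of the i-th non-gap residue.

        For a '+' row this is ``start + i``; for a '-' row the printed start
        counts from the 3' end, so the forward position is
        ``srcSize - 1 - (start + i)``.
        """
        if not 0 <= i < self.size:
            raise IndexError(f"residue index {i} out of range [0, {self.size})")
        if self.strand == "+":
            return self.start + i
        return self.src_size - 1 - (self.start + i)

    def column_residue_indices(self) -> list[int]:
        """Map column -> residue index i (or -1 for gap columns). Cached."""
        if self._col_to_residue_index is None:
            out = []
            i = 0
            for ch in self.text:
                if ch == GAP:
                    out.append(-1)
                else:
                    out.append(i)
                    i += 1
            self._col_to_residue_index = out
        return self._col_to_residue_index

    def residue_at_column(self, col: int) -> Residue | None:
        """Residue occupying a column of this row, or None on a gap."""
        i = self.column_residue_indices()[col]
        if i < 0:
            return None
        genome, chrom = split_sequence_name(self.seq_name)
        return Residue(genome, chrom, self.forward_position(i))


@dataclass
class MafBlock:
    """One 'a' paragraph of a MAF file: an ordered set of rows of equal width."""

    rows: list[MafRow] = field(default_factory=list)
    score: float | None = None

    @property
    def ncols(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def validate(self, allow_all_gap_columns: bool = False) -> None:
        for row in self.rows:
            row.validate()
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise MafError(f"rows of unequal width {sorted(widths)} in block")
        if not allow_all_gap_columns:
            for col in range(self.ncols):
                if all(r.text[col] == GAP for r in self.rows):
                    raise MafError(f"column {col} consists entirely of gaps")

    def column_residues(self, col: int) -> list[Residue]:
        """Residues of the non-gap rows in a column, in row order."""
        out = []
        for row in self.rows:
            res = row.residue_at_column(col)
            if res is not None:
                out.append(res)
        return out

    def genomes(self) -> set[str]:
        return {r.genome for r in self.rows}


def _open_maybe_gzip(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_maf(source: str | IO[str]) -> Iterator[MafBlock]:
    """Lazily yield :class:`MafBlock` objects from a MAF file or text stream.

    ``i``/``e``/``q`` annotation lines are accepted and discarded; ``#``
    comment lines are skipped.  Malformed ``s`` lines raise
    :class:`MafParseError` naming the offending line number.  Blocks containing
    an all-gap column are tolerated with a warning (writers refuse them).
    """
    if isinstance(source, str):
        handle: IO[str] = _open_maybe_gzip(source)
        own = True
    else:
        handle, own = source, False
    try:
        block: MafBlock | None = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if block is not None and block.rows:
                    _finish_block(block, lineno)
                    yield block
                block = None
                continue
            tag = line.split(None, 1)[0]
            if tag.startswith("#"):
                continue
            if tag == "a":
                if block is not None and block.rows:
                    _finish_block(block, lineno)
                    yield block
                score = None
                for tok in line.split()[1:]:
                    if tok.startswith("score="):
                        try:
                            score = float(tok[6:])
                        except ValueError as exc:
                            raise MafParseError(f"bad score {tok!r}", lineno) from exc
                block = MafBlock(score=score)
            elif tag == "s":
                if block is None:
                    raise MafParseError("'s' line outside of an 'a' block", lineno)
                block.rows.append(_parse_s_line(line, lineno))
            elif tag in ("i", "e", "q"):
                continue  # row metadata; nothing in scope consumes it
            else:
                raise MafParseError(f"unrecognised line type {tag!r}", lineno)
        if block is not None and block.rows:
            _finish_block(block, None)
            yield block
    finally:
        if own:
            handle.close()


def _parse_s_line(line: str, lineno: int) -> MafRow:
    fields = line.split()
    if len(fields) != 7:
        raise MafParseError(
            f"'s' line has {len(fields)} fields, expected 7", lineno
        )
    _, seq_name, start, size, strand, src_size, text = fields
    try:
        row = MafRow(seq_name, int(start), int(size), strand, int(src_size), text)
    except ValueError as exc:
        raise MafParseError(f"non-integer coordinate field: {exc}", lineno) from exc
    try:
        row.validate()
    except MafError as exc:
        raise MafParseError(str(exc), lineno) from exc
    return row


def _finish_block(block: MafBlock, lineno: int | None) -> None:
    try:
        block.validate(allow_all_gap_columns=True)
    except MafError as exc:
        raise MafParseError(str(exc), lineno)
    for col in range(block.ncols):
        if all(r.text[col] == GAP for r in block.rows):
            warnings.warn(f"block ending near line {lineno}: all-gap column {col}")
            break


def read_maf(source: str | IO[str]) -> list[MafBlock]:
    """Read a whole MAF file into memory."""
    return list(parse_maf(source))


def write_maf(blocks: Iterable[MafBlock], dest: str | IO[str]) -> None:
    """Write blocks as a MAF v1 file; refuses blocks violating invariants."""
    if isinstance(dest, str):
        handle: IO[str] = open(dest, "wt", encoding="utf-8")
        own = True
    else:
        handle, own = dest, False
    try:
        handle.write("##maf version=1\n")
        for block in blocks:
            block.validate(allow_all_gap_columns=False)
            handle.write("\n")
            if block.score is not None:
                handle.write(f"a score={block.score}\n")
            else:
                handle.write("a\n")
            name_w = max(len(r.seq_name) for r in block.rows)
            start_w = max(len(str(r.start)) for r in block.rows)
            size_w = max(len(str(r.size)) for r in block.rows)
            src_w = max(len(str(r.src_size)) for r in block.rows)
            for r in block.rows:
                handle.write(
                    f"s {r.seq_name:<{name_w}} {r.start:>{start_w}} "
                    f"{r.size:>{size_w}} {r.strand} {r.src_size:>{src_w}} {r.text}\n"
                )
    finally:
        if own:
            handle.close()
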