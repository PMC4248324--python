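"""Regional sub-sampling of alignments and 1-kb score tracks.

Genome-scale statistical scoring is expensive, so reliability metrics are
computed on a handful of fixed-length windows of a reference genome (the
defaults mirror common practice: five windows of 500 kb).  Windows are drawn
uniformly over the concatenated reference and mapped back to chromosomes;
draws that straddle a chromosome boundary are rejected and redrawn, and
overlapping windows are permitted but logged.

Within a window, the reference is cut into fixed non-overlapping bins
(default 1 kb) and a score — F-score against a truth alignment, or the
truth-free pseudo F-score — is computed for each bin exhaustively, as if the
bin's pairs were a complete alignment.  A pair belongs to a bin when at least
one of its residues is a reference residue inside the bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .comparator import f_score
from .maf import GAP, MafBlock, MafRow, Residue
from .psar import PsarScores, pseudo_f
from .relation import ResiduePair, iter_pairs

logger = logging.getLogger(__name__)

DEFAULT_N_REGIONS = 5
DEFAULT_WINDOW = 500_000
DEFAULT_BIN = 1_000

__all__ = [
    "Region",
    "sample_regions",
    "extract_region",
    "bin_scores",
    "DEFAULT_N_REGIONS",
    "DEFAULT_WINDOW",
    "DEFAULT_BIN",
]


@dataclass(frozen=True)
class Region:
    """A 0-based half-open interval on one reference sequence."""

    seq_name: str  # full "genome.chrom" name
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def sample_regions(
    chrom_sizes: Mapping[str, int],
    n: int = DEFAULT_N_REGIONS,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> list[Region]:
    """Draw n windows uniformly over the concatenated reference genome.

    Start values come from a discrete uniform on [0, g - 1 - window] where g
    is the total genome length, then map back to individual chromosomes;
    windows crossing a chromosome boundary are redrawn.  Overlaps between
    windows are allowed (a warning is logged when they occur).
    """
    names = sorted(chrom_sizes)
    sizes = [chrom_sizes[name] for name in names]
    g = sum(sizes)
    if g <= window:
        raise ValueError(f"genome length {g} not greater than window {window}")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    rng = np.random.default_rng(seed)
    regions: list[Region] = []
    while len(regions) < n:
        start = int(rng.integers(0, g - window))  # upper bound g-1-window inclusive
        chrom_i = int(np.searchsorted(offsets, start, side="right")) - 1
        local = start - int(offsets[chrom_i])
        if local + window > sizes[chrom_i]:
            continue  # straddles a chromosome boundary: redraw
        regions.append(Region(names[chrom_i], local, local + window))
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1 :]:
            if r1.seq_name == r2.seq_name and r1.start < r2.end and r2.start < r1.end:
                logger.warning("sampled regions overlap: %s and %s", r1, r2)
    return regions


def _trim_block(block: MafBlock, ref_rows: list[MafRow], region: Region) -> MafBlock | None:
    """Trim a block to the columns whose reference residue lies in the region."""
    anchor = ref_rows[0]
    col_map = anchor.column_residue_indices()
    in_cols = [
        c
        for c in range(block.ncols)
        if col_map[c] >= 0 and region.start <= anchor.forward_position(col_map[c]) < region.end
    ]
    if not in_cols:
        return None
    lo, hi = in_cols[0], in_cols[-1]
    rows: list[MafRow] = []
    for row in block.rows:
        text = row.text[lo : hi + 1]
        size = len(text) - text.count(GAP)
        if size == 0:
            continue
        leading = len(row.text[:lo]) - row.text[:lo].count(GAP)
        rows.append(
            MafRow(
                seq_name=row.seq_name,
                start=row.start + leading,
                size=size,
                strand=row.strand,
                src_size=row.src_size,
                text=text,
            )
        )
    # drop columns left entirely gapped by removed rows
    keep = [c for c in range(hi - lo + 1) if any(r.text[c] != GAP for r in rows)]
    if len(keep) != hi - lo + 1:
        for i, row in enumerate(rows):
            text = "".join(row.text[c] for c in keep)
            rows[i] = MafRow(
                row.seq_name, row.start, row.size, row.strand, row.src_size, text
            )
    return MafBlock(rows=rows) if rows else None


def extract_region(blocks, region: Region) -> list[MafBlock]:
    """Sub-MAF of the blocks intersecting a reference window.

    Blocks with at least one reference residue inside the window are kept and
    trimmed column-wise to the window (columns whose reference residue falls
    outside are cut; a multi-copy reference block is anchored on its first
    reference row); blocks without the reference are dropped.
    """
    blocks = list(blocks)
    if not any(region.seq_name in {r.seq_name for r in b.rows} for b in blocks):
        raise ValueError(f"reference sequence {region.seq_name!r} absent from MAF")
    out = []
    for block in blocks:
        ref_rows = [r for r in block.rows if r.seq_name == region.seq_name]
        if not ref_rows:
            continue
        trimmed = _trim_block(block, ref_rows, region)
        if trimmed is not None:
            out.append(trimmed)
    return out


def _ref_bin(pair: ResiduePair, region: Region, bin_size: int, ref_genome: str, ref_chrom: str):
    """Bin indices (possibly two) a pair belongs to via its reference residues."""
    bins = set()
    for res in pair:
        if (
            res.genome == ref_genome
            and res.chrom == ref_chrom
            and region.start <= res.pos < region.end
        ):
            bins.add((res.pos - region.start) // bin_size)
    return bins


def bin_scores(
    pred_region: Sequence[MafBlock],
    region: Region,
    bin_size: int = DEFAULT_BIN,
    truth_region: Sequence[MafBlock] | None = None,
    psar_scores: PsarScores | None = None,
    mode: str = "f_score",
) -> list[tuple[Region, float | None]]:
    """Per-bin score track across a reference window.

    ``f_score`` mode computes exhaustive precision/recall of the prediction's
    bin pair set against the truth's (both restricted to pairs with a
    reference residue in the bin).  ``pseudo_f`` mode combines the mean PSAR
    pair score of the bin's scored pairs with the bin's reference coverage
    (fraction of the bin's reference residues aligned to another genome,
    averaged over genomes).  Bins with no pairs yield None (missing), not 0.
    """
    from .maf import split_sequence_name

    ref_genome, ref_chrom = split_sequence_name(region.seq_name)
    n_bins = (region.length + bin_size - 1) // bin_size
    pred_bins: list[set[ResiduePair]] = [set() for _ in range(n_bins)]
    for pair in iter_pairs(pred_region):
        for b in _ref_bin(pair, region, bin_size, ref_genome, ref_chrom):
            pred_bins[b].add(pair)

    def bin_region(b: int) -> Region:
        lo = region.start + b * bin_size
        return Region(region.seq_name, lo, min(lo + bin_size, region.end))

    out: list[tuple[Region, float | None]] = []
    if mode == "f_score":
        if truth_region is None:
            raise ValueError("f_score mode needs a truth region")
        true_bins: list[set[ResiduePair]] = [set() for _ in range(n_bins)]
        for pair in iter_pairs(truth_region):
            for b in _ref_bin(pair, region, bin_size, ref_genome, ref_chrom):
                true_bins[b].add(pair)
        for b in range(n_bins):
            pred_set, true_set = pred_bins[b], true_bins[b]
            if not pred_set and not true_set:
                out.append((bin_region(b), None))
                continue
            inter = len(pred_set & true_set)
            p = inter / len(pred_set) if pred_set else 0.0
            r = inter / len(true_set) if true_set else 0.0
            out.append((bin_region(b), f_score(p, r)))
    elif mode == "pseudo_f":
        if psar_scores is None:
            raise ValueError("pseudo_f mode needs PSAR scores")
        for b in range(n_bins):
            pairs = pred_bins[b]
            if not pairs:
                out.append((bin_region(b), None))
                continue
            scored = [psar_scores.scores[p] for p in pairs if p in psar_scores.scores]
            if not scored:
                out.append((bin_region(b), None))
                continue
            precision = sum(scored) / len(scored)
            cov = _bin_coverage(pairs, bin_region(b), ref_genome, ref_chrom)
            out.append((bin_region(b), pseudo_f(precision, cov)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def _bin_coverage(
    pairs: set[ResiduePair], bin_reg: Region, ref_genome: str, ref_chrom: str
) -> float:
    """Mean over non-reference genomes of the bin's reference coverage."""
    per_genome: dict[str, set[int]] = {}
    for a, b in pairs:
        for res, other in ((a, b), (b, a)):
            if (
                res.genome == ref_genome
                and res.chrom == ref_chrom
                and bin_reg.start <= res.pos < bin_reg.end
                and other.genome != ref_genome
            ):
                per_genome.setdefault(other.genome, set()).add(res.pos)
    if not per_genome:
        return 0.0
    width = bin_reg.length
    return sum(len(v) / width for v in per_genome.values()) / len(per_genome)
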