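"""Coverage metrics: truth-free proxies for recall and duplication content.

Coverage of genome B on genome A is the proportion of A's residues aligned to
at least one residue of B — a recall proxy requiring no truth alignment.  The
overall coverage averages this over ordered pairs of distinct genomes.
Duplicative coverage of B on A is the proportion of A's residues aligned to
two or more *distinct* residues of B; it is meaningful on a transitively
closed alignment, where multi-alignment of one residue cannot hide in
separate columns (callers normally run the closure first).

Denominators are genome sizes: the sum of srcSize over the distinct sequences
of a genome observed anywhere in the MAF, overridable with an explicit
chromosome-sizes map for genomes whose unaligned chromosomes never appear.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .maf import MafBlock

__all__ = [
    "genome_sizes",
    "pairwise_coverage",
    "overall_coverage",
    "duplicative_coverage",
    "coverage_matrix",
]


def genome_sizes(
    blocks: Iterable[MafBlock],
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Total residue count per genome (sum of srcSize over distinct sequences)."""
    seen: dict[tuple[str, str], int] = {}
    for block in blocks:
        for row in block.rows:
            seen[(row.genome, row.chrom)] = row.src_size
    totals: dict[str, int] = {}
    for (genome, _), size in seen.items():
        totals[genome] = totals.get(genome, 0) + size
    if chrom_sizes:
        # explicit sizes are authoritative; keys are "genome.chrom" or genome
        override: dict[str, int] = {}
        for name, size in chrom_sizes.items():
            genome = name.partition(".")[0]
            override[genome] = override.get(genome, 0) + size
        totals.update(override)
    return totals


def _partner_counts(
    blocks: list[MafBlock], genome_a: str, genome_b: str
) -> dict[tuple[str, int], set]:
    """For each residue of A (keyed by (chrom, pos)), the distinct B partners."""
    partners: dict[tuple[str, int], set] = {}
    for block in blocks:
        for col in range(block.ncols):
            residues = block.column_residues(col)
            a_res = [r for r in residues if r.genome == genome_a]
            b_res = [r for r in residues if r.genome == genome_b]
            if not a_res or not b_res:
                continue
            for a in a_res:
                bucket = partners.setdefault((a.chrom, a.pos), set())
                for b in b_res:
                    if b != a:
                        bucket.add((b.chrom, b.pos))
    return partners


def _check_genomes(blocks: list[MafBlock], *genomes: str) -> None:
    present = set()
    for block in blocks:
        present |= block.genomes()
    for g in genomes:
        if g not in present:
            raise ValueError(f"genome {g!r} absent from the alignment")


def pairwise_coverage(
    blocks,
    genome_a: str,
    genome_b: str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> float:
    """Proportion of A's residues aligned to >=1 residue of B (asymmetric)."""
    if genome_a == genome_b:
        raise ValueError("pairwise coverage requires two distinct genomes")
    blocks = list(blocks)
    _check_genomes(blocks, genome_a, genome_b)
    total = genome_sizes(blocks, chrom_sizes).get(genome_a, 0)
    if total == 0:
        raise ValueError(f"genome {genome_a!r} has zero total size")
    covered = sum(
        1 for bucket in _partner_counts(blocks, genome_a, genome_b).values() if bucket
    )
    return covered / total


def overall_coverage(
    blocks,
    genomes: Iterable[str] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    ordered: bool = True,
) -> float:
    """Mean pairwise coverage over all ordered pairs of distinct genomes.

    Coverage is asymmetric, so the ordered mean is the default; the unordered
    mode averages the two directions of each pair first.
    """
    blocks = list(blocks)
    if genomes is None:
        genomes = sorted(genome_sizes(blocks))
    genomes = sorted(genomes)
    if len(genomes) < 2:
        raise ValueError("overall coverage needs at least two genomes")
    values = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            cab = pairwise_coverage(blocks, ga, gb, chrom_sizes)
            cba = pairwise_coverage(blocks, gb, ga, chrom_sizes)
            if ordered:
                values.extend([cab, cba])
            else:
                values.append((cab + cba) / 2.0)
    return sum(values) / len(values)


def duplicative_coverage(
    blocks,
    genome_a: str,
    genome_b: str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> float:
    """Proportion of A's residues aligned to >=2 distinct residues of B.

    A == B is permitted and measures self-duplication.  The input should be
    transitively closed; this function does not run the closure itself.
    """
    blocks = list(blocks)
    _check_genomes(blocks, genome_a, genome_b)
    total = genome_sizes(blocks, chrom_sizes).get(genome_a, 0)
    if total == 0:
        raise ValueError(f"genome {genome_a!r} has zero total size")
    dup = sum(
        1
        for bucket in _partner_counts(blocks, genome_a, genome_b).values()
        if len(bucket) >= 2
    )
    return dup / total


def coverage_matrix(
    blocks,
    duplicative: bool = False,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[str], list[list[float]]]:
    """All ordered pairwise (duplicative) coverages as (genomes, matrix).

    matrix[i][j] = coverage of genome j on genome i; the diagonal is 0 for
    plain coverage and self-duplicative coverage in duplicative mode.
    """
    blocks = list(blocks)
    genomes = sorted(genome_sizes(blocks))
    fn = duplicative_coverage if duplicative else pairwise_coverage
    matrix = []
    for ga in genomes:
        row = []
        for gb in genomes:
            if ga == gb and not duplicative:
                row.append(0.0)
            else:
                row.append(fn(blocks, ga, gb, chrom_sizes))
        matrix.append(row)
    return genomes, matrix
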