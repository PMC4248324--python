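# Methods

This note documents the models, estimators and design choices behind
`wgaeval`, in the order a user meets them.

## The alignment relation and its coordinate model

All metrics are defined on the *alignment relation*: the set of unordered
residue pairs co-occurring in alignment columns.  Pair identity is
orientation-free — every residue is addressed by its absolute position on the
forward strand of its chromosome, so a pair reported on the minus strand by
one aligner and on the plus strand by another is the same pair.  MAF row
starts are strand-relative (UCSC dialect, 0-based); the conversion for a '-'
row maps the i-th residue to `srcSize - 1 - (start + i)`.  Genome identity is
the prefix of the sequence name before the first dot (`genome.chrom`), the
convention of MAF producers; soft-masking case is preserved on I/O and
ignored by every metric.  `i`/`e`/`q` annotation lines are parsed and
discarded: nothing in scope consumes them.

Intra-genome pairs (two residues of one genome in a column, i.e.
duplications) are part of the relation by default and can be excluded with a
filter; whether a published comparator counted them is not knowable from its
description, so both modes exist and the default is the more inclusive one,
consistent with duplications being an assessment target.

## Sampled precision / recall

Exhaustive intersection of two relations is infeasible at genome scale, so
the comparator samples.  Pass 1 counts the eligible pairs m; pass 2 revisits
every column and draws `x ~ Binomial(k, min(1, s/m))` for a column with k
eligible pairs, then samples x distinct integers without replacement from
[0, k) and maps them to pairs through a bijective row-major index
(0,1),(0,2),…,(1,2),…  The expected draw total is s; each pair occurrence is
equally likely; no column's pairs are ever materialised unless sampled.  The
two passes observe identical eligibility because the comparator re-traverses
the blocks rather than caching derived state.  At s ≥ m the clamp makes every
pair drawn exactly once, so estimates become exact intersection ratios — the
property the test suite exploits.  Default s is 10,000,000 per direction;
each direction consumes its own seeded generator in file order, so a
comparison is reproducible given (files, s, seed).  Reported standard errors
are plain binomial `sqrt(f(1-f)/n)`; no finite-population correction is
applied because the sampling fraction at default s is tiny.

Stratified comparison restricts eligibility by annotation: a pair belongs to
a BED stratum when **either** residue lies in the stratum's intervals (a
`both_residues` strict mode exists; "either" keeps strata populated when
annotations exist for only some genomes).  Species-pair comparison uses only
inter-genome pairs of the two genomes, plus aggregates over all pairs and
over reference-containing pairs.

The Jaccard distance between two relations is estimated from the two directed
overlap fractions: with pA the fraction of A's sample found in B and pB the
converse, the intersection estimate is `I = (pA·mA + pB·mB)/2` and the
distance `1 - I/(mA + mB - I)`, clamped to [0, 1].

## Transitive closure

Homology is transitive; MAF is not forced to be.  The closure unions residues
within every column (union-find with path compression, near-linear in residue
occurrences) and emits each equivalence class of size ≥ 2 as one column,
merging runs of classes with identical composition and positions advancing by
one into maximal gapless blocks.  Classes holding several residues of one
genome are preserved as multi-row-per-genome blocks — required for
duplicative coverage, which is measured after closure.  The output is emitted
on the '+' strand at forward positions; original strand context and block
scores are not reconstructed (the operation is relation-level and documented
as lossy).  Closedness is tested structurally: a relation is closed iff its
distinct pair count equals Σ C(|class|, 2).

## Coverage and duplicative coverage

Coverage of B on A = (A residues aligned to ≥1 B residue) / |A|; duplicative
coverage replaces ≥1 by "≥2 distinct".  |A| is the sum of srcSize over the
distinct sequences of A seen anywhere in the file — MAFs may omit unaligned
chromosomes entirely, so an explicit chromosome-sizes table can override.
Overall coverage averages the **ordered** pairs of distinct genomes (coverage
is asymmetric and "all pairs of distinct species" does not disambiguate; an
unordered mode averages the two directions first).  Duplicative coverage does
not run the closure itself; the CLI pipeline closes first by default.

## PSAR-style reliability

The scorer follows the leave-one-out scheme: remove a row, sample suboptimal
re-alignments of it against the profile of the remaining rows, and score each
originally aligned pair by the fraction of samples reproducing it, averaging
the votes of the pair's two rows.  The model is the standard 3-state pair-HMM
(match M, gaps X/Y, no X↔Y transitions, start in M, no end penalty); sampling
is stochastic traceback from the forward matrix, which draws each path with
probability proportional to its forward contribution, so the per-pair vote
converges to the forward-backward posterior (verified in tests against exact
path enumeration on tiny instances).

Parameter defaults are generic DNA-alignment settings, all configurable:
match-state emission probability 0.85 on the identical base (the remaining
0.15 split over the three mismatches; N is a 0.25 wildcard), gap open
δ = 0.02, gap extend ε = 0.7, gap-state emissions uniform 0.25.  A profile
column's emission is the arithmetic mean of per-residue match emissions over
its non-gap rows; gap-heavy columns simply contribute fewer rows.  The
original scorer's exact parameterization and sample count are not published,
so this implementation fixes its own and labels the metric PSAR-*style*; no
bit-compatibility is claimed.  Default 100 samples per row.  Leave-one-out
runs for every row including the reference.  Scores for residues dropped
during matrix preparation (duplicate genome copies) are absent, not zero.

Preparation of a regional MAF for scoring keeps, per genome per block, the
row sharing the most columns with the reference row; blocks are concatenated
in reference order into one matrix, rows ordered reference-first then by
decreasing residue count, all-gap columns dropped.

PSAR-precision of a genome pair is the mean pair score over its aligned
residues; the overall value averages the per-pair precisions over
reference-containing pairs.  The pseudo F-score is the harmonic mean of
PSAR-precision and coverage.

## Regional sampling and bin tracks

Windows (default five of 500 kb, matching common practice at genome scale)
are drawn uniformly over the concatenated reference, mapped back to
chromosomes, redrawn if they straddle a boundary, and allowed to overlap
(logged).  Extraction keeps blocks with ≥1 reference residue in the window
and trims columns whose reference residue falls outside (an untrimmed mode
exists); trimming makes the bins partition the region's reference pairs
cleanly.  Bins (default 1 kb) are anchored at the window start, the last bin
may be short; a pair belongs to a bin when at least one of its residues is a
reference residue in the bin, and bin scores are computed exhaustively, as if
the bin's pairs were a complete alignment.  Empty bins are missing, not zero.
In pseudo-F mode a bin's coverage is the fraction of its reference residues
aligned to each other genome, averaged over genomes.

## Phylogenetic utilities

Newick parsing and tree arithmetic use dendropy; missing branch lengths
default to 0 with a warning.  Leaf path length is the patristic distance.
UPGMA is average-linkage agglomeration (scipy linkage behind the module's
surface) with labels sorted first so ties break by label order; leaves sit at
height 0 and each merge at half its distance, so an ultrametric input is
reproduced exactly.

## The toy simulator and corruptor

The simulator evolves a uniform-random root sequence down a tree.  Per branch
of length t over a sequence of length L, event counts are Poisson with means
`rate · t · L`: substitutions (rate 1 by default; each event moves the base to
one of the other three uniformly, i.e. Jukes-Cantor, giving the closed form
p_diff = (3/4)(1 − e^(−4t/3)) used as a test oracle), indels (rate 0.05,
geometric lengths of mean 3, insertions carrying fresh origin ids), inversions
and tandem duplications (rates 0 by default, enabled where an analysis needs
them; geometric lengths of mean 20).  Every residue carries the identity of
the single ancestral residue it descends from; duplication copies share it,
so both copies stay homologous to the ancestor's other descendants and to
each other.  Two leaf residues are truly homologous iff they share this
origin — an equivalence relation, so the truth map is transitively closed by
construction, and homologies predating the root are excluded because origins
are created at the root or later.  The truth MAF chains co-linear origin
classes into maximal blocks, emitting inverted members on the '-' strand.
Annotation labels (genic 30%, neutral 50%, repetitive 20%, geometric segments
of mean 200 bp — a plausible toy layout; "neutral" is simply the complement
of the other two) are laid on the root and propagate to leaves through each
residue's origin key.

The corruptor retains each truth pair independently with probability
`target_recall`, then injects false pairs — a retained pair with one residue
shifted by a random offset of up to 50 bp onto a position not aligned to the
other — until retained/(retained+injected) equals `target_precision` up to
rounding, erroring if the position space cannot supply enough false pairs.
The result is written as chained two-row blocks, each column asserting
exactly one pair, so the output relation equals the constructed set exactly
and no transitive conflicts can arise; exact precision/recall of the output
are therefore known by construction, which is what makes the comparator
testable.

What the simulator does **not** emulate: mobile-element libraries, gene and
protein models, rate heterogeneity, translocations, chromosome
fission/fusion, realistic repeat structure, or assembly artifacts.  Passing
tests therefore demonstrate correctness of the estimators and algorithms on
relations with realistic event geometry at desk scale, not aligner behaviour
on real mammalian genomes.

## Numerical and scale choices

The pair-HMM runs in log space; stochastic traceback renormalises the three
predecessor weights per step.  UPGMA and closure tie-breaks are lexicographic
for determinism.  Test and acceptance problem sizes (root sequences of
600–5,000 bp for relation metrics, 20,000–100,000 bp for the Jukes-Cantor
check, 100 PSAR samples per row, windows of a few hundred bp) were chosen so
the full suite runs in minutes on one CPU while keeping Monte-Carlo error
well inside the asserted 3-standard-error bands.  Degenerate inputs are
errors, not silent zeros: empty relations, empty samples, absent genomes and
out-of-range probabilities all raise, while empty annotation strata and empty
bins are reported as empty/missing.

## Known limitations

- The PSAR-style scores are not bit-compatible with the published PSAR tool;
  parameterization is this package's own.
- Closure output discards original strand context and block scores.
- Coverage denominators trust srcSize (or an explicit sizes table); whether
  assembly N-gaps should be excluded is input-dependent and not second-guessed.
- In-memory indices only: the toolkit targets desk-scale relations (≤ ~10^7
  pairs comfortably), not disk-backed full-mammal workflows.
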