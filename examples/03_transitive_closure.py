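"""Enforce homology transitivity on a MAF and measure duplications.

A MAF may align x~y and y~z in separate blocks without asserting x~z.  The
transitive closure merges such chains into single columns; duplicative
coverage (the fraction of one genome's residues aligned to two or more
residues of another) is then well defined.
"""

import io

import wgaeval as w

CHAIN = """##maf version=1
a
s human.chr1 10 4 + 100 ACGT
s chimp.chr1 20 4 + 100 ACGT

a
s chimp.chr1 20 4 + 100 ACGT
s gorilla.chr1 30 4 + 100 ACGT
"""

blocks = w.read_maf(io.StringIO(CHAIN))
print("transitively closed?", w.is_transitively_closed(blocks))

closed = w.transitive_closure(blocks)
print("after closure:", len(closed), "block,", len(closed[0].rows), "rows")
print("pairs before:", w.count_pairs(blocks), "-> after:", w.count_pairs(closed))
# The human~gorilla pairs implied by the shared chimp residues appear only
# after closure: 8 asserted pairs become 12 (4 columns x 3 pairs).

dup = w.duplicative_coverage(closed, "human", "chimp")
print(f"duplicative coverage of chimp on human = {dup:.3f} (no duplications here)")
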