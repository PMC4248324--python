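import io
import random

import pytest

import wgaeval as w

PRIMATE_NEWICK = (
    "((simGorilla:0.008825,(simHuman:0.0067,simChimp:0.006667)"
    "sHuman-sChimp:0.00225)sG-sH-sC:0.00968,simOrang:0.018318);"
)

THREE_LEAF_TREE = "((A:0.08,B:0.08):0.05,C:0.12);"


@pytest.fixture(scope="session")
def primate_newick() -> str:
    return PRIMATE_NEWICK


@pytest.fixture(scope="session")
def toy_truth() -> w.ToyGenomeSet:
    """A small three-genome truth set with substitutions and indels."""
    return w.evolve(
        THREE_LEAF_TREE, 1500, w.EvolParams(indel_rate=0.03), seed=20240901
    )


@pytest.fixture(scope="session")
def toy_truth_events() -> w.ToyGenomeSet:
    """Truth set exercising inversions and duplications too."""
    return w.evolve(
        THREE_LEAF_TREE,
        1500,
        w.EvolParams(indel_rate=0.03, inv_rate=0.002, dup_rate=0.002),
        seed=20240902,
    )


def random_maf(rng: random.Random, n_blocks: int = 3, width: int = 8) -> list[w.MafBlock]:
    """A random small MAF over a tiny shared coordinate space.

    Overlapping starts make residues recur across blocks, so transitive
    closure is usually non-trivial.
    """
    genomes = ["A", "B", "C"]
    blocks = []
    for _ in range(n_blocks):
        rows = []
        for genome in rng.sample(genomes, rng.randint(2, 3)):
            start = rng.randint(0, 40)
            text = "".join(
                rng.choice("ACGT-") if rng.random() < 0.3 else rng.choice("ACGT")
                for _ in range(width)
            )
            size = len(text) - text.count("-")
            if size == 0:
                text = "A" + text[1:]
                size = 1
            rows.append(
                w.MafRow(f"{genome}.c", start, size, "+", 64, text)
            )
        # ensure no all-gap columns
        cols = [
            c for c in range(width) if all(r.text[c] == "-" for r in rows)
        ]
        for c in cols:
            r0 = rows[0]
            rows[0] = w.MafRow(
                r0.seq_name, r0.start, r0.size + 1, r0.strand, r0.src_size,
                r0.text[:c] + "A" + r0.text[c + 1:],
            )
        blocks.append(w.MafBlock(rows=rows))
    return blocks


def naive_closure_relation(blocks) -> set:
    """Brute-force transitive closure by repeated joining, for oracle use."""
    pairs = set(w.iter_pairs(blocks))
    changed = True
    while changed:
        changed = False
        partners: dict = {}
        for a, b in pairs:
            partners.setdefault(a, set()).add(b)
            partners.setdefault(b, set()).add(a)
        for res, mates in partners.items():
            mates = sorted(mates)
            for i in range(len(mates)):
                for j in range(i + 1, len(mates)):
                    pair = w.make_pair(mates[i], mates[j])
                    if pair not in pairs:
                        pairs.add(pair)
                        changed = True
    return pairs


def maf_text(blocks) -> str:
    out = io.StringIO()
    w.write_maf(blocks, out)
    return out.getvalue()
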