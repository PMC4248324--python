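"""Phylogenetic utilities: newick trees, leaf distances, UPGMA clustering.

Leaf-to-leaf path lengths (sums of branch lengths) stratify accuracy metrics
by evolutionary distance; UPGMA (average-linkage agglomeration) turns a
Jaccard-distance matrix over alignments into a dendrogram of their
similarity.  Trees are dendropy objects; UPGMA runs on scipy's average
linkage behind this module's surface, with labels sorted lexicographically so
tie-breaking is deterministic and documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = ["parse_newick", "write_newick", "leaf_path_length", "DistanceMatrix", "upgma"]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string (branch lengths expected, internal labels optional)."""
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    missing = [
        e for e in tree.preorder_edge_iter() if e.head_node.parent_node and e.length is None
    ]
    if missing:
        import warnings

        warnings.warn(f"{len(missing)} branches without length; defaulting to 0")
        for e in missing:
            e.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_path_length(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if a == b:
        if tree.taxon_namespace.get_taxon(a) is None:
            raise KeyError(f"unknown leaf label {a!r}")
        return 0.0
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    if ta is None or tb is None:
        missing = a if ta is None else b
        raise KeyError(f"unknown leaf label {missing!r}")
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(ta, tb))


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix has a nonzero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


def upgma(matrix: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomerative clustering into an ultrametric tree.

    Labels are sorted before clustering so that ties in minimal distance are
    broken by label order.  Branch lengths place every leaf at height 0 and
    each internal node at half the merge distance (ultrametric by
    construction): on an ultrametric input the tree reproduces the pairwise
    distances exactly.
    """
    if len(matrix.labels) < 2:
        raise ValueError("UPGMA needs at least two labels")
    order = sorted(range(len(matrix.labels)), key=lambda i: matrix.labels[i])
    labels = [matrix.labels[i] for i in order]
    values = matrix.values[np.ix_(order, order)]
    link = linkage(squareform(values, checks=False), method="average")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, label in enumerate(labels):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[i] = (node, 0.0)
    n = len(labels)
    for step, (ia, ib, dist, _count) in enumerate(link):
        height = dist / 2.0
        child_a, ha = nodes[int(ia)]
        child_b, hb = nodes[int(ib)]
        parent = dendropy.Node()
        child_a.edge.length = height - ha
        child_b.edge.length = height - hb
        parent.add_child(child_a)
        parent.add_child(child_b)
        nodes[n + step] = (parent, height)
    root, _ = nodes[n + len(link) - 1]
    tree.seed_node = root
    return tree
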