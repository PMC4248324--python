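"""Cluster alignments by the Jaccard distance between their pair relations.

Three corrupted versions of one truth are compared all-vs-all; alignments
sharing more aligned pairs sit closer in the UPGMA dendrogram.
"""

import numpy as np

import wgaeval as w

truth = w.evolve("((A:0.06,B:0.06):0.04,C:0.1);", 1500, seed=3)
preds = {
    "good": w.corrupt(truth, 0.95, 0.9, seed=1),
    "good2": w.corrupt(truth, 0.95, 0.9, seed=2),
    "poor": w.corrupt(truth, 0.6, 0.5, seed=3),
}

names = sorted(preds)
n = len(names)
matrix = np.zeros((n, n))
s = 2 * len(truth.truth_pairs)
for i in range(n):
    for j in range(i + 1, n):
        d = w.jaccard_distance(preds[names[i]], preds[names[j]], s=s, seed=9)
        matrix[i, j] = matrix[j, i] = d

print("Jaccard distance matrix:")
print("\t" + "\t".join(names))
for name, row in zip(names, matrix):
    print(name + "\t" + "\t".join(f"{v:.3f}" for v in row))

tree = w.upgma(w.DistanceMatrix(names, matrix))
print("UPGMA:", w.write_newick(tree))
# The two 'good' corruptions share most retained pairs and cluster together;
# the 'poor' one is the outgroup.
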