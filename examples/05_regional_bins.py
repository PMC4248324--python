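"""Visualise regional accuracy: per-bin F-score track across a window.

The reference window is cut into fixed bins; each bin is scored exhaustively
as if its pairs were a complete alignment, exposing where in the genome a
prediction degrades.
"""

import wgaeval as w
from wgaeval.regional import Region

truth = w.evolve("((A:0.06,B:0.06):0.04,C:0.1);", 2000, w.EvolParams(indel_rate=0.02), seed=5)
pred = w.corrupt(truth, 0.85, 0.75, seed=6)

region = Region("A.chr1", 0, 1000)
pred_sub = w.extract_region(pred, region)
truth_sub = w.extract_region(truth.truth_maf, region)

track = w.bin_scores(pred_sub, region, bin_size=100, truth_region=truth_sub)
print("bin\tF-score")
for bin_region, score in track:
    bar = "" if score is None else "#" * int(score * 40)
    text = "NA" if score is None else f"{score:.3f}"
    print(f"{bin_region.start}-{bin_region.end}\t{text}\t{bar}")
# Bins where the corruptor removed or shifted pairs score below 1; empty bins
# are reported as missing (NA), not zero.
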