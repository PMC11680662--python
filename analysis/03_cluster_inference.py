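#!/usr/bin/env python
"""Group-level cluster inference on the demo decoding time courses.

Loads scratch/demo/accuracy.h5 (produced by 02_simulate_and_decode.py),
runs the single-condition sign-flip cluster permutation test per ROI and
condition plus the dual-constraint between-condition tests (words vs.
nonwords; CV- vs. -VC overlap), gates with Bonferroni over the 5 simulated
ROIs, and writes results/clusters.tsv.
"""

from pathlib import Path

from wordform.cluster import (between_condition_clusters, bonferroni_gate,
                              single_condition_clusters)
from wordform.io import clusters_to_frame, load_decoding_h5

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 7

dec = load_decoding_h5(ROOT / "scratch" / "demo" / "accuracy.h5")
n_rois = dec.accuracy.shape[1]

records = []
for ci, cond in enumerate(dec.conditions):
    for roi in range(n_rois):
        records.extend(single_condition_clusters(
            dec.accuracy[:, roi, ci, :], dec.times, roi=roi, condition=cond,
            n_perm=1000, seed=SEED + 3))
for contrast in (("words_only", "nonwords_only"), ("cv_overlap", "vc_overlap")):
    ia = dec.conditions.index(contrast[0])
    ib = dec.conditions.index(contrast[1])
    for roi in range(n_rois):
        ab, ba = between_condition_clusters(
            dec.accuracy[:, roi, ia, :], dec.accuracy[:, roi, ib, :],
            dec.times, roi=roi, condition_pair=contrast, n_perm=1000,
            seed=SEED + 4)
        records.extend(ab + ba)

flags = bonferroni_gate([r.p_value for r in records], n_rois=n_rois)
for r, f in zip(records, flags):
    r.significant = bool(f)

df = clusters_to_frame(records)
df.to_csv(RESULTS / "clusters.tsv", sep="\t", index=False)
sig = df[df.significant]
print(f"{len(df)} clusters tested, {len(sig)} significant after Bonferroni "
      f"over {n_rois} ROIs:")
if sig.empty:
    print("  none")
else:
    print(sig.to_string(index=False))
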