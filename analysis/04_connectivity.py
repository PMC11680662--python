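#!/usr/bin/env python
"""Decoding-informed effective connectivity on the demo study.

Regenerates the demo epochs deterministically (same seeds as
02_simulate_and_decode.py), loads the word-trained decoding accuracy, and
runs the Kalman-MVAR Granger analysis over the ROIs with significant
word-trained clusters (from results/clusters.tsv), using ROIs 3-4 as the
non-decoding control pair.  Writes results/gc.tsv.
"""

from pathlib import Path

import pandas as pd

from wordform.connectivity import run_connectivity
from wordform.design import DesignConfig, make_schedule
from wordform.io import gc_results_to_frame, load_decoding_h5
from wordform.preprocess import preprocess
from wordform.synth import (CouplingEdge, GroundTruth, mark_behavioral_errors,
                            simulate_subject)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 7

config = DesignConfig(n_subjects=12, n_rois=5)
truth = GroundTruth.random(
    config,
    lexical_rois=[0, 1], lexical_amp=0.55, lexical_window=(250.0, 700.0),
    segmental_rois=[0], segmental_amp=0.8,
    amp_mod_sd=0.5, seed=42,
    coupling_edges=(CouplingEdge(0, 1, 20.0, 1.0),),
)
schedule = make_schedule(config, SEED)
epochs = {}
for s in range(config.n_subjects):
    ep = simulate_subject(schedule, truth, config, s)
    ep = mark_behavioral_errors(ep, 0.08, 0.14, seed=SEED + 1)
    epochs[s] = preprocess(ep)

dec = load_decoding_h5(ROOT / "scratch" / "demo" / "accuracy.h5")
wi = dec.conditions.index("words_only")

clusters = pd.read_csv(RESULTS / "clusters.tsv", sep="\t")
decoding_rois = sorted(clusters[(clusters.condition == "words_only")
                                & clusters.significant]["roi"].unique())
print(f"word-trained decoding ROIs: {decoding_rois}")

results = run_connectivity(
    epochs, dec.accuracy[:, :, wi, :], dec.times, list(decoding_rois),
    control_pair=(3, 4), n_surrogates=100, seed=SEED + 5)
df = gc_results_to_frame(results)
df.to_csv(RESULTS / "gc.tsv", sep="\t", index=False)
print(df.to_string(index=False))
sig = df[df.fdr_significant]
print(f"{len(sig)} FDR-significant directed interactions"
      + ("" if sig.empty else
         f"; reciprocal: {int(sig.reciprocal.sum())}"))
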