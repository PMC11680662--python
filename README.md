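# wordform

Transfer-learning neural decoding and decoding-informed effective
connectivity for phonological wordform representations in source-space
MEG/EEG — with a synthetic-data generator that emulates the underlying
lexical-decision experiment, so the complete analysis chain runs and can
be validated without any recordings.

## The scientific problem

When someone hears *pig*, which brain regions carry the stored
sound-pattern (wordform) of that word, as opposed to transient acoustic
or phonemic detail? The design this package implements answers that with
a transfer test. Six CVC hub words each define a phonological
neighborhood of one-phoneme neighbors — three real words (*pick*-like)
and three nonwords (*pid*-like), the changed position counterbalanced
over onset, vowel and coda. A linear SVM is trained, at every timepoint,
to discriminate two neighborhoods using only *neighbor* trials, then
tested on the corresponding *hub* words it never saw. Above-chance
transfer requires representational structure shared between neighbors and
hub: early in the epoch that structure is segmental overlap (present for
word and nonword neighbors alike), but after the word has been recognized
it can only be a consolidated lexical representation — which nonword
neighbors do not have. Regions whose transfer decoding succeeds with
word-trained but not nonword-trained classifiers are therefore candidate
wordform areas. A second stage asks whether those regions' activity
*drives* processing elsewhere: a Kalman-filter adaptive MVAR Granger
analysis tests whether one region's subdivision time courses improve
prediction of another region's moment-by-moment decoding accuracy in the
250–550 ms window, beyond all other regions' activity.

The statistical machinery is: pseudo-trial averaging (random bins of 8
trials, 100 assignments), per-timepoint pairwise SVM transfer decoding
(chance = 0.5), cluster-based sign-flip permutation tests over time with
Bonferroni control across 39 ROIs (p < 0.05/39 = 0.00128), a
dual-constraint between-condition cluster test, and binomial tests of
significant-GC-timepoint counts against a non-decoding control ROI pair
with Benjamini–Hochberg FDR over directed pairs.

Because the real recordings are not consumed here, the package ships a
generative model (`wordform.synth`) whose ground truth — which ROIs carry
segmental or lexical patterns, in which windows, and which ROI drives
which — is explicit, so every stage can be checked against what was
injected. `docs/methods.md` describes the model and every statistical
choice in detail.

## Worked example

Simulate two subjects with a strong lexical pattern in ROI 0 at
400–600 ms (ROI 1 is noise), preprocess, and run transfer decoding with
word-trained and nonword-trained classifiers:

```python
import numpy as np
from wordform import (DesignConfig, GroundTruth, build_stimulus_set,
                      make_schedule, simulate_subject, decode_study)
from wordform.preprocess import preprocess

config = DesignConfig(n_subjects=2, n_rois=2)
truth = GroundTruth.random(config, lexical_rois=[0], lexical_amp=1.5,
                           lexical_window=(400, 600), seed=21)
schedule = make_schedule(config, seed=0)
items = build_stimulus_set(config)
epochs = {s: preprocess(simulate_subject(schedule, truth, config, s))
          for s in range(2)}
dec = decode_study(epochs, items, conditions=("words_only", "nonwords_only"),
                   n_assignments=5, seed=3,
                   time_indices=np.arange(0, 1101, 25))
w = (dec.times >= 400) & (dec.times < 600)
for ci, cond in enumerate(dec.conditions):
    a = dec.accuracy[:, :, ci, :]
    print(f"{cond:>14s}: ROI0 in-window {a[:,0,w].mean():.3f}, "
          f"ROI1 in-window {a[:,1,w].mean():.3f}, "
          f"ROI0 late {a[:,0,dec.times>=700].mean():.3f}")
```

prints

```
    words_only: ROI0 in-window 0.986, ROI1 in-window 0.476, ROI0 late 0.505
 nonwords_only: ROI0 in-window 0.509, ROI1 in-window 0.501, ROI0 late 0.511
```

Word-trained classifiers transfer almost perfectly to the untrained hubs
inside the lexical window of the ROI that carries the wordform pattern —
and sit at the 0.5 chance level for nonword training, for the noise ROI,
and outside the window, exactly the signature that separates lexical from
sublexical decoding.

The numbered scripts under `analysis/` run the full demo study: design
tables (`01`), simulation + decoding in all four training conditions
(`02`), cluster inference (`03`) and effective connectivity (`04`), each
writing its table under `results/`. For example `01_design_schedule.py`
prints:

```
stimulus set: 42 items, 6 hubs, 18 nonwords
schedule: 16 blocks x 48 trials, 8 talkers x 96 trials
hub-adjacency violations (brute-force scan): 0
```

A consolidated CLI covers the two shell-level entry points:
`wordform make-schedule --seed 0 --out schedule.tsv` and
`wordform run --out outdir/` (end-to-end demo study).

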