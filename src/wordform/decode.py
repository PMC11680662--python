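"""Per-timepoint pairwise transfer decoding.

For each pair of neighborhoods (A, B) and each training condition, a
binary linear SVM is trained at each timepoint on bin-averaged *neighbor*
trials of A vs. B (the items returned by
:func:`wordform.design.select_training_items`) and tested on the
corresponding bin-averaged *hub* trials — stimuli the classifier never saw.
Above-chance transfer therefore requires representational structure shared
between neighbors and hubs.  Accuracy is averaged over the 100 random bin
assignments, then over all 15 neighborhood pairs, yielding one accuracy
time course per subject x ROI x condition (chance = 0.5).

Features at a timepoint are the ROI's 8 normalized subdivision values at
that single timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, StimulusItem, neighborhood_pairs, select_training_items
from .preprocess import BinAssignment, average_bins, make_bins
from .svm import accuracy_over_time, decision_values, fit_linear_svm
from .synth import EpochTensor

__all__ = [
    "DecodingTimecourse",
    "train_test_timepoint",
    "condition_groups",
    "transfer_decode",
    "aggregate_pairs",
    "decode_subject",
    "decode_study",
]


@dataclass
class DecodingTimecourse:
    """Transfer decoding accuracy: subjects x ROIs x conditions x timepoints."""

    accuracy: np.ndarray
    times: np.ndarray
    conditions: tuple[str, ...]
    subjects: tuple[int, ...]
    chance: float = 0.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.accuracy.ndim != 4:
            raise ValueError("accuracy must be 4-d (subjects, rois, conditions, times)")
        if self.accuracy.shape[3] != self.times.size:
            raise ValueError("time axis mismatch")
        if self.accuracy.min() < 0.0 or self.accuracy.max() > 1.0:
            raise ValueError("accuracies must lie in [0, 1]")

    def condition(self, name: str) -> np.ndarray:
        """(subjects, rois, times) slice for one training condition."""
        return self.accuracy[:, :, self.conditions.index(name), :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (subject, roi, condition, time_ms, accuracy)."""
        S, R, C, T = self.accuracy.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, range(R), self.conditions, self.times],
            names=["subject", "roi", "condition", "time_ms"],
        )
        return pd.DataFrame({"accuracy": self.accuracy.ravel()}, index=idx).reset_index()


def train_test_timepoint(train_features, train_labels, test_features, test_labels,
                         C: float = 1.0) -> float:
    """Accuracy of one SVM fold at a single timepoint.

    Labels identify the hub/neighborhood class and may be any two values;
    the first label in sorted order plays class A (+1), toward which
    decision-boundary ties are broken.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    classes = np.unique(ytr)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 training classes, got {classes.size}")
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("train/test feature dimension mismatch")
    if yte.size == 0:
        raise ValueError("need at least one test sample")
    s_tr = np.where(ytr == classes[0], 1.0, -1.0)
    s_te = np.where(yte == classes[0], 1.0, -1.0)
    w, b = fit_linear_svm(Xtr, s_tr, C=C)
    pred = np.where(decision_values(Xte, w, b) >= 0.0, 1.0, -1.0)
    return float(np.mean(pred == s_te))


def condition_groups(trials: pd.DataFrame, items: list[StimulusItem],
                     conditions: tuple[str, ...] = CONDITIONS) -> dict[str, np.ndarray]:
    """Trial-index groups for binning: hub and per-condition training groups.

    Keys: ``hub:<k>`` (hub trials of neighborhood k) and
    ``train:<condition>:<k>`` (trials of that condition's training items).
    """
    labels = trials["item_label"].to_numpy()
    nbhds = sorted({it.neighborhood_id for it in items})
    groups: dict[str, np.ndarray] = {}
    for k in nbhds:
        hub_label = next(it.label for it in items
                         if it.neighborhood_id == k and it.role == "hub")
        groups[f"hub:{k}"] = np.flatnonzero(labels == hub_label)
        for cond in conditions:
            train_labels = {it.label for it in select_training_items(items, k, cond)}
            groups[f"train:{cond}:{k}"] = np.flatnonzero(
                np.isin(labels, sorted(train_labels)))
    return groups


def transfer_decode(
    epochs: EpochTensor,
    roi: int,
    pair: tuple[int, int],
    condition: str,
    assignments: list[BinAssignment],
    time_indices: np.ndarray | None = None,
    C: float = 1.0,
) -> np.ndarray:
    """Mean-over-assignments transfer accuracy time course for one ROI and pair.

    Trains on neighbor bins of neighborhoods ``pair[0]`` (class A) vs.
    ``pair[1]`` (class B) and tests on the corresponding hub bins; asserts
    on every assignment that training and test trials are disjoint.
    """
    if not (epochs.baseline_corrected and epochs.normalized):
        raise ValueError("epochs must be baseline-corrected and normalized")
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct neighborhoods")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    tidx = (np.arange(epochs.times.size) if time_indices is None
            else np.asarray(time_indices))
    sl = epochs.roi_slice(roi)
    data = epochs.data[:, sl, :][:, :, tidx]

    acc = np.zeros(tidx.size)
    for asg in assignments:
        tr_a = asg.bins[f"train:{condition}:{a}"]
        tr_b = asg.bins[f"train:{condition}:{b}"]
        te_a = asg.bins[f"hub:{a}"]
        te_b = asg.bins[f"hub:{b}"]
        train_idx = np.concatenate(tr_a + tr_b)
        test_idx = np.concatenate(te_a + te_b)
        if np.intersect1d(train_idx, test_idx).size:
            raise AssertionError("transfer integrity violated: train/test overlap")
        Xtr = np.concatenate([average_bins(data, tr_a), average_bins(data, tr_b)])
        Xte = np.concatenate([average_bins(data, te_a), average_bins(data, te_b)])
        ytr = np.concatenate([np.ones(len(tr_a)), -np.ones(len(tr_b))])
        yte = np.concatenate([np.ones(len(te_a)), -np.ones(len(te_b))])
        acc += accuracy_over_time(Xtr, ytr, Xte, yte, C=C)
    return acc / len(assignments)


def aggregate_pairs(per_pair: dict[tuple[int, int], np.ndarray],
                    n_neighborhoods: int = 6) -> np.ndarray:
    """Unweighted mean accuracy over all unordered neighborhood pairs."""
    expected = neighborhood_pairs(n_neighborhoods)
    missing = [p for p in expected if p not in per_pair]
    if missing:
        raise ValueError(f"missing neighborhood pairs: {missing}")
    return np.mean([per_pair[p] for p in expected], axis=0)


def decode_subject(
    epochs: EpochTensor,
    items: list[StimulusItem],
    conditions: tuple[str, ...] = CONDITIONS,
    n_assignments: int = 100,
    bin_size: int = 8,
    seed: int = 0,
    time_indices: np.ndarray | None = None,
    rois: list[int] | None = None,
    pairs: list[tuple[int, int]] | None = None,
    C: float = 1.0,
) -> np.ndarray:
    """Accuracy array (rois, conditions, times) for one subject.

    Uses one shared set of bin assignments across ROIs and conditions, as
    binning operates on trials, not channels.  ``pairs`` may restrict the
    neighborhood pairs (all 15 by default, which engages the
    ``aggregate_pairs`` completeness check).
    """
    groups = condition_groups(epochs.trials, items, conditions)
    assignments = make_bins(epochs.trials, groups, bin_size=bin_size,
                            n_assignments=n_assignments, seed=seed)
    roi_list = list(range(epochs.n_rois)) if rois is None else list(rois)
    tidx = (np.arange(epochs.times.size) if time_indices is None
            else np.asarray(time_indices))
    full = pairs is None
    pair_list = neighborhood_pairs() if full else pairs

    out = np.zeros((len(roi_list), len(conditions), tidx.size))
    for ri, roi in enumerate(roi_list):
        for ci, cond in enumerate(conditions):
            per_pair = {
                p: transfer_decode(epochs, roi, p, cond, assignments, tidx, C=C)
                for p in pair_list
            }
            if full:
                out[ri, ci] = aggregate_pairs(per_pair)
            else:
                out[ri, ci] = np.mean(list(per_pair.values()), axis=0)
    return out


def decode_study(
    epochs_by_subject: dict[int, EpochTensor],
    items: list[StimulusItem],
    conditions: tuple[str, ...] = CONDITIONS,
    n_assignments: int = 100,
    bin_size: int = 8,
    seed: int = 0,
    time_indices: np.ndarray | None = None,
    rois: list[int] | None = None,
    pairs: list[tuple[int, int]] | None = None,
    C: float = 1.0,
) -> DecodingTimecourse:
    """Transfer decoding for every subject; returns a DecodingTimecourse."""
    subjects = tuple(sorted(epochs_by_subject))
    first = epochs_by_subject[subjects[0]]
    tidx = (np.arange(first.times.size) if time_indices is None
            else np.asarray(time_indices))
    acc = np.stack([
        decode_subject(
            epochs_by_subject[s], items, conditions, n_assignments, bin_size,
            seed=np.random.SeedSequence([seed, s]).generate_state(1)[0] % (2**31),
            time_indices=tidx, rois=rois, pairs=pairs, C=C,
        )
        for s in subjects
    ])
    return DecodingTimecourse(
        accuracy=acc,
        times=first.times[tidx],
        conditions=tuple(conditions),
        subjects=subjects,
        provenance={
            "n_assignments": n_assignments,
            "bin_size": bin_size,
            "seed": seed,
            "pairs": "all" if pairs is None else list(map(list, pairs)),
        },
    )
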