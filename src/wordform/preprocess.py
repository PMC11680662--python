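"""Preprocessing of ROI-subdivision epochs.

Four steps sit between raw (synthetic or imported) epochs and decoding:
subtraction of the 100-ms pre-stimulus baseline, vector normalization of
the subdivision pattern at every timepoint, restriction to correct-response
trials, and random averaging of trials into bins of eight ("pseudo-trials")
to raise SNR, repeated over 100 independent bin assignments.

State flags on the tensor guard against double application: each step
checks and sets ``baseline_corrected`` / ``normalized``.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

from .synth import EpochTensor

__all__ = [
    "BinAssignment",
    "baseline_correct",
    "vector_normalize",
    "make_bins",
    "average_bins",
    "preprocess",
]


def baseline_correct(epochs: EpochTensor) -> EpochTensor:
    """Subtract the mean over the pre-stimulus period per epoch and channel."""
    if epochs.baseline_corrected:
        raise ValueError("epochs are already baseline corrected")
    pre = epochs.times < 0.0
    if not pre.any():
        raise ValueError("no pre-stimulus samples to form a baseline")
    out = epochs.copy(data=epochs.data - epochs.data[:, :, pre].mean(axis=2, keepdims=True))
    out.baseline_corrected = True
    return out


def vector_normalize(epochs: EpochTensor, scope: str = "roi") -> EpochTensor:
    """Scale the subdivision pattern to unit Euclidean norm at every timepoint.

    ``scope="roi"`` (default) normalizes each ROI's 8-subdivision vector
    independently, so each ROI contributes a pure pattern direction to its
    decoder; ``scope="global"`` normalizes across all channels jointly.
    Exact-zero vectors are left at zero rather than producing NaNs.
    """
    if not epochs.baseline_corrected:
        raise ValueError("baseline-correct before vector normalization")
    if epochs.normalized:
        raise ValueError("epochs are already normalized")
    if scope not in ("roi", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    n_tr, C, T = epochs.data.shape
    if scope == "roi":
        S = epochs.n_subdivisions
        R = C // S
        x = epochs.data.reshape(n_tr, R, S, T)
        norms = np.linalg.norm(x, axis=2, keepdims=True)
        data = np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)
        data = data.reshape(n_tr, C, T)
    else:
        norms = np.linalg.norm(epochs.data, axis=1, keepdims=True)
        data = np.divide(epochs.data, norms, out=np.zeros_like(epochs.data),
                         where=norms > 0)
    out = epochs.copy(data=data)
    out.normalized = True
    return out


@dataclass
class BinAssignment:
    """One random grouping of correct trials into disjoint bins per condition."""

    assignment_id: int
    bins: dict[str, list[np.ndarray]]       # condition -> list of index arrays
    leftovers: dict[str, np.ndarray]        # condition -> dropped indices

    def to_json(self) -> str:
        return json.dumps({
            "assignment_id": self.assignment_id,
            "bins": {c: [b.tolist() for b in bs] for c, bs in self.bins.items()},
            "leftovers": {c: lo.tolist() for c, lo in self.leftovers.items()},
        })


def make_bins(
    trials: pd.DataFrame,
    condition_groups: dict[str, np.ndarray],
    bin_size: int = 8,
    n_assignments: int = 100,
    seed: int = 0,
) -> list[BinAssignment]:
    """Random disjoint bins of correct trials, repeated ``n_assignments`` times.

    ``condition_groups`` maps a condition name to the trial indices that
    belong to it.  Within each assignment and condition, the correct trials
    are randomly permuted and chopped into ``floor(n/bin_size)`` bins of
    exactly ``bin_size``; the remainder is dropped for that assignment.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    correct = trials["correct"].to_numpy()
    pools: dict[str, np.ndarray] = {}
    for cond, idx in condition_groups.items():
        idx = np.asarray(idx, dtype=int)
        pool = idx[correct[idx]]
        if len(pool) < bin_size:
            raise ValueError(
                f"condition {cond!r} has only {len(pool)} correct trials "
                f"(need at least {bin_size})"
            )
        pools[cond] = pool

    rng = np.random.default_rng(seed)
    out = []
    for a in range(n_assignments):
        bins: dict[str, list[np.ndarray]] = {}
        leftovers: dict[str, np.ndarray] = {}
        for cond, pool in pools.items():
            perm = rng.permutation(pool)
            n_bins = len(perm) // bin_size
            bins[cond] = [perm[i * bin_size:(i + 1) * bin_size] for i in range(n_bins)]
            leftovers[cond] = perm[n_bins * bin_size:]
        out.append(BinAssignment(a, bins, leftovers))
    return out


def average_bins(data: np.ndarray, bins: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of the member epochs of each bin.

    ``data`` is (trials, ...); returns (n_bins, ...) with row *i* the mean
    of ``data[bins[i]]``.
    """
    n = data.shape[0]
    for b in bins:
        if len(b) and (b.min() < 0 or b.max() >= n):
            raise IndexError("bin index out of range for tensor")
    return np.stack([data[b].mean(axis=0) for b in bins])


def preprocess(epochs: EpochTensor, scope: str = "roi") -> EpochTensor:
    """Baseline-correct then vector-normalize."""
    return vector_normalize(baseline_correct(epochs), scope=scope)
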