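"""Group-level cluster-based sign-flip permutation inference.

Decoding-accuracy time courses are tested across subjects against the
pairwise chance level of 0.5.  Clusters are maximal runs of consecutive
timepoints whose one-tailed one-sample t-test (cluster-forming alpha 0.05)
is significant; the cluster statistic is the run length.  The null is
built by randomly flipping each subject's deviation from chance (a +-1
Rademacher variable per subject per permutation), recording the largest
cluster per permutation; the cluster p-value is the smoothed exceedance
fraction (k+1)/(n_perm+1).  Family-wise control over ROIs is Bonferroni
(0.05/39 = 0.00128 under the full ROI family).

The between-condition test adds a dual constraint: a timepoint joins an
A-over-B cluster only if condition A is above chance (uncorrected 0.05)
AND the paired A-B difference is significant (uncorrected 0.05, with the
mean difference in A's favor).  Its null flips, independently per subject,
both the deviation of the condition mean from chance and the A-B
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ClusterRecord",
    "pointwise_above_chance",
    "paired_difference_mask",
    "find_clusters",
    "max_run_lengths",
    "permutation_null_single",
    "cluster_p_value",
    "bonferroni_gate",
    "single_condition_clusters",
    "between_condition_clusters",
]


@dataclass
class ClusterRecord:
    roi: int
    condition: str
    start_ms: float
    end_ms: float
    size: int
    p_value: float
    significant: bool = False

    def __post_init__(self) -> None:
        if self.start_ms > self.end_ms:
            raise ValueError("start_ms must be <= end_ms")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")


def _one_tailed_t(dev: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic of mean(dev) > 0 across axis 0; zero-variance cells get
    +-inf according to the sign of the mean (0 if the mean is 0 too)."""
    S = dev.shape[0]
    m = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(S))
    t = np.where(sd == 0, np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0)), t)
    return t, S - 1


def pointwise_above_chance(acc: np.ndarray, chance: float = 0.5,
                           alpha: float = 0.05) -> np.ndarray:
    """Timepoint mask where accuracy exceeds chance across subjects.

    One-tailed one-sample t-test of (acc - chance) over axis 0 (subjects).
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2:
        raise ValueError("need a (subjects, timepoints) array with >= 2 subjects")
    t, df = _one_tailed_t(acc - chance)
    return t > stats.t.ppf(1.0 - alpha, df)


def paired_difference_mask(acc_a: np.ndarray, acc_b: np.ndarray,
                           alpha: float = 0.05) -> np.ndarray:
    """Mask where the paired two-tailed test finds A different from B,
    with the mean difference favoring A."""
    d = np.asarray(acc_a, float) - np.asarray(acc_b, float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need matched (subjects, timepoints) arrays, >= 2 subjects")
    t, df = _one_tailed_t(d)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return (np.abs(t) > crit) & (d.mean(axis=0) > 0)


def find_clusters(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of True: list of (start_index, end_index, size), end inclusive."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1:
        raise ValueError("mask must be 1-d")
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [(int(s), int(e), int(e - s + 1)) for s, e in zip(starts, ends)]


def max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Largest run of True per row of a 2-d boolean array (vectorized)."""
    m = np.asarray(masks, dtype=bool)
    c = np.cumsum(m, axis=1)
    reset = np.where(~m, c, 0)
    carried = np.maximum.accumulate(reset, axis=1)
    return (c - carried).max(axis=1)


def permutation_null_single(acc: np.ndarray, n_perm: int = 1000, seed: int = 0,
                            chance: float = 0.5, alpha: float = 0.05) -> np.ndarray:
    """Null distribution of the maximum cluster size under per-subject sign flips.

    Each permutation multiplies every subject's deviation from chance by an
    independent +-1 and recomputes the pointwise test and clustering.  The
    squared deviations are flip-invariant, so the permuted t statistics are
    computed in closed form for all permutations at once.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2:
        raise ValueError("need a (subjects, timepoints) array with >= 2 subjects")
    S, T = acc.shape
    d = acc - chance
    ssq = (d ** 2).sum(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, S)) * 2 - 1
    m = (signs @ d) / S
    var = (ssq[None, :] - S * m ** 2) / (S - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / S)
    t = np.where(var == 0, np.where(m > 0, np.inf, -np.inf), t)
    masks = t > stats.t.ppf(1.0 - alpha, S - 1)
    return max_run_lengths(masks)


def cluster_p_value(size: int, null_sizes: np.ndarray) -> float:
    """Smoothed permutation p-value (k+1)/(n_perm+1)."""
    n_perm = len(null_sizes)
    return (int(np.sum(null_sizes >= size)) + 1) / (n_perm + 1)


def bonferroni_gate(p_values: np.ndarray, n_rois: int = 39,
                    alpha: float = 0.05) -> np.ndarray:
    """Significance flags under Bonferroni control over the ROI family."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() <= 0.0 or p.max() > 1.0):
        raise ValueError("p-values must be in (0, 1]")
    return p < alpha / n_rois


def single_condition_clusters(
    acc: np.ndarray,
    times: np.ndarray,
    roi: int = 0,
    condition: str = "",
    n_perm: int = 1000,
    seed: int = 0,
    chance: float = 0.5,
    alpha: float = 0.05,
) -> list[ClusterRecord]:
    """Observed above-chance clusters with permutation p-values (ungated)."""
    mask = pointwise_above_chance(acc, chance=chance, alpha=alpha)
    clusters = find_clusters(mask)
    if not clusters:
        return []
    null = permutation_null_single(acc, n_perm=n_perm, seed=seed,
                                   chance=chance, alpha=alpha)
    return [
        ClusterRecord(roi, condition, float(times[s]), float(times[e]), size,
                      cluster_p_value(size, null))
        for s, e, size in clusters
    ]


def _dual_masks(acc_a: np.ndarray, acc_b: np.ndarray, chance: float,
                alpha: float) -> tuple[np.ndarray, np.ndarray]:
    above_a = pointwise_above_chance(acc_a, chance, alpha)
    above_b = pointwise_above_chance(acc_b, chance, alpha)
    diff_a = paired_difference_mask(acc_a, acc_b, alpha)
    diff_b = paired_difference_mask(acc_b, acc_a, alpha)
    return above_a & diff_a, above_b & diff_b


def between_condition_clusters(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    times: np.ndarray,
    roi: int = 0,
    condition_pair: tuple[str, str] = ("A", "B"),
    n_perm: int = 1000,
    seed: int = 0,
    chance: float = 0.5,
    alpha: float = 0.05,
) -> tuple[list[ClusterRecord], list[ClusterRecord]]:
    """Dual-constraint between-condition clusters for A>B and B>A.

    The permutation null flips, independently per subject, the deviation of
    the within-subject condition mean from chance and the A-B difference;
    each permutation's statistic is the largest cluster over both
    directions, giving one null for the two-direction family.
    """
    acc_a = np.asarray(acc_a, float)
    acc_b = np.asarray(acc_b, float)
    if acc_a.shape != acc_b.shape:
        raise ValueError("condition arrays must have matching shapes")
    if acc_a.ndim != 2 or acc_a.shape[0] < 2:
        raise ValueError("need matched (subjects, timepoints) arrays, >= 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    S, T = acc_a.shape

    mask_ab, mask_ba = _dual_masks(acc_a, acc_b, chance, alpha)
    obs = {"ab": find_clusters(mask_ab), "ba": find_clusters(mask_ba)}
    if not (obs["ab"] or obs["ba"]):
        return [], []

    u = 0.5 * (acc_a + acc_b) - chance
    d = acc_a - acc_b
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=int)
    for p in range(n_perm):
        s1 = rng.integers(0, 2, size=(S, 1)) * 2 - 1
        s2 = rng.integers(0, 2, size=(S, 1)) * 2 - 1
        up = s1 * u
        dp = s2 * d
        pa = chance + up + 0.5 * dp
        pb = chance + up - 0.5 * dp
        m_ab, m_ba = _dual_masks(pa, pb, chance, alpha)
        null[p] = max(max_run_lengths(m_ab[None, :])[0],
                      max_run_lengths(m_ba[None, :])[0])

    def records(key: str, name: str) -> list[ClusterRecord]:
        return [
            ClusterRecord(roi, name, float(times[s]), float(times[e]), size,
                          cluster_p_value(size, null))
            for s, e, size in obs[key]
        ]

    a_name = f"{condition_pair[0]}>{condition_pair[1]}"
    b_name = f"{condition_pair[1]}>{condition_pair[0]}"
    return records("ab", a_name), records("ba", b_name)
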