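"""Decoding-informed time-varying Granger causality between ROIs.

The question: does the event-related subdivision activity of a *source*
ROI improve one-step prediction of a *target* ROI's decoding-accuracy time
course, beyond the target's own history and every other ROI's activity?
Node signals substitute for the classical MVAR channels as follows: the
target node carries its scalar within-subject transfer-decoding accuracy
time course (word-trained, averaged over neighborhood pairs); every other
ROI contributes its 8 subdivision event-related time courses.  Analysis is
restricted to a 250-550 ms window (the lexical N400 latency range).

An adaptive MVAR model is estimated with a Kalman filter whose state is
the coefficient vector of the target equation, evolving as a random walk
with a scalar adaptation constant; the innovation variance is tracked with
an exponentially weighted estimator.  The GC index at time t is
``ln(reduced error variance / full error variance)``, floored at zero,
where the reduced model omits the source ROI's channels.  Per-timepoint
significance is calibrated against circular-time-shift surrogates of the
source channels.  A directed pair's strength is the count of significant
timepoints in the window, compared with a non-decoding control pair by a
one-tailed exact binomial test, with Benjamini-Hochberg FDR over the
candidate directed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import EpochTensor

__all__ = [
    "GCResult",
    "assemble_node_signals",
    "compress_predictors",
    "kalman_mvar_gc",
    "gc_significance",
    "binomial_vs_control",
    "fdr_correct",
    "run_connectivity",
]


@dataclass
class GCResult:
    source_roi: int
    target_roi: int
    gc_index: np.ndarray
    sig_mask: np.ndarray
    window: tuple[float, float]
    sig_count: int
    window_len: int
    binomial_p: float = 1.0
    fdr_significant: bool = False
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if self.sig_count > self.window_len:
            raise ValueError("sig_count cannot exceed window_len")


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    m = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return np.divide(x - m, sd, out=np.zeros_like(x), where=sd > 0)


def assemble_node_signals(
    epochs: EpochTensor,
    acc: np.ndarray,
    acc_times: np.ndarray,
    target_roi: int,
    decoding_rois: list[int] | None = None,
    window: tuple[float, float] = (250.0, 550.0),
    require_decoding: bool = True,
) -> tuple[np.ndarray, dict[int, np.ndarray], np.ndarray]:
    """Multichannel node signals for one subject and target ROI.

    Channel 0 is the target's decoding-accuracy time course (interpolated
    onto the epoch grid inside the window); the remaining channels are the
    event-related subdivision time courses (mean over correct trials) of
    every other ROI — ``(n_rois - 1) * n_subdivisions + 1`` channels in
    total, all z-scored over the window.  Returns (signals, roi_channels,
    window_times) with ``roi_channels`` mapping each predictor ROI to its
    channel rows.
    """
    if require_decoding:
        if decoding_rois is None or target_roi not in decoding_rois:
            raise ValueError(
                f"target ROI {target_roi} is not in the decoding ROI set")
    win = (epochs.times >= window[0]) & (epochs.times <= window[1])
    times_win = epochs.times[win]
    correct = epochs.trials["correct"].to_numpy()
    erf = epochs.data[correct].mean(axis=0)[:, win]         # (C, T_win)
    acc_win = np.interp(times_win, acc_times, acc)

    S = epochs.n_subdivisions
    rows = [acc_win[None, :]]
    roi_channels: dict[int, np.ndarray] = {}
    nxt = 1
    for r in range(epochs.n_rois):
        if r == target_roi:
            continue
        rows.append(erf[r * S:(r + 1) * S])
        roi_channels[r] = np.arange(nxt, nxt + S)
        nxt += S
    signals = _zscore_rows(np.concatenate(rows, axis=0))
    return signals, roi_channels, times_win


def compress_predictors(
    signals: np.ndarray,
    roi_channels: dict[int, np.ndarray],
    source_roi: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce non-source predictor ROIs to their first principal component.

    The target channel (row 0) and the tested source ROI keep all their
    channels; every other ROI is represented by the leading PC of its
    subdivision time courses.  Keeps the full-ROI conditioning set at a
    dimension the short analysis window can support.  Returns
    (compressed_signals, source_rows).
    """
    if source_roi not in roi_channels:
        raise ValueError(f"source ROI {source_roi} not among predictors")
    rows = [signals[0:1]]
    src = signals[roi_channels[source_roi]]
    source_rows = np.arange(1, 1 + src.shape[0])
    rows.append(src)
    for r, ch in roi_channels.items():
        if r == source_roi:
            continue
        block = signals[ch]
        # leading left singular vector projects the block to one time course
        u, s, vt = np.linalg.svd(block, full_matrices=False)
        rows.append((u[:, 0] @ block)[None, :])
    return _zscore_rows(np.concatenate(rows, axis=0)), source_rows


@njit(cache=False)
def _kalman_errvar(X, target, use, order, q, lam):
    """One-step innovation-variance track of an adaptive AR model.

    Predicts X[target, t] from `order` lags of the channels in `use` (plus
    an intercept).  Coefficients follow a random walk (state noise q on the
    diagonal); the innovation variance is an EW average with constant lam.
    Entries before `order` repeat the first defined value.
    """
    C = use.shape[0]
    T = X.shape[1]
    d = 1 + order * C
    w = np.zeros(d)
    P = np.eye(d)
    Rv = 1.0
    ev = np.zeros(T)
    h = np.empty(d)
    for t in range(order, T):
        h[0] = 1.0
        k = 1
        for lag in range(1, order + 1):
            for c in range(C):
                h[k] = X[use[c], t - lag]
                k += 1
        for i in range(d):
            P[i, i] += q
        Ph = P @ h
        Sv = h @ Ph + Rv
        e = X[target, t] - w @ h
        K = Ph / Sv
        w += K * e
        P -= np.outer(K, Ph)
        for i in range(d):
            for j in range(i + 1, d):
                v = 0.5 * (P[i, j] + P[j, i])
                P[i, j] = v
                P[j, i] = v
        Rv = (1.0 - lam) * Rv + lam * e * e
        ev[t] = Rv
    for t in range(order):
        ev[t] = ev[order] if T > order else 1.0
    return ev


def kalman_mvar_gc(
    signals: np.ndarray,
    source_channels: np.ndarray,
    target_index: int = 0,
    order: int = 5,
    adapt_const: float = 0.02,
    err_smooth: float = 0.5,
) -> np.ndarray:
    """GC-index time course for (source -> target) on one signal matrix.

    ``signals`` is (channels, timepoints).  The full model predicts the
    target from all channels' lags; the reduced model omits the source
    channels.  gc(t) = max(0, ln(reduced_var(t) / full_var(t))).

    ``adapt_const`` scales the coefficient random walk; ``err_smooth`` is
    the separate EW constant of the innovation-variance track and sets the
    temporal locality of the GC index (time constant ~1/err_smooth
    samples).
    """
    signals = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")
    if order < 1:
        raise ValueError("order must be >= 1")
    C, T = signals.shape
    if T <= order + 1:
        raise ValueError(f"series length {T} too short for order {order}")
    src = np.asarray(source_channels, dtype=np.int64)
    all_ch = np.arange(C, dtype=np.int64)
    reduced = np.array([c for c in all_ch if c not in set(src.tolist())],
                       dtype=np.int64)
    q = adapt_const ** 2
    ev_full = _kalman_errvar(signals, target_index, all_ch, order, q, err_smooth)
    ev_red = _kalman_errvar(signals, target_index, reduced, order, q, err_smooth)
    with np.errstate(divide="ignore"):
        gc = np.log(ev_red / ev_full)
    return np.maximum(gc, 0.0)


def gc_significance(gc_index: np.ndarray, surrogate_ensemble: np.ndarray,
                    alpha: float = 0.05) -> np.ndarray:
    """Per-timepoint mask: observed GC above the (1-alpha) surrogate quantile."""
    surr = np.asarray(surrogate_ensemble, dtype=float)
    if surr.ndim != 2 or surr.shape[0] < 100:
        raise ValueError("need a (>=100, timepoints) surrogate ensemble")
    if alpha >= 1.0:
        return np.ones(gc_index.shape, dtype=bool)
    thresh = np.quantile(surr, 1.0 - alpha, axis=0)
    return np.asarray(gc_index) > thresh


def binomial_vs_control(sig_count: int, window_len: int,
                        control_rate: float) -> float:
    """One-tailed exact binomial tail P(X >= sig_count | n, control_rate)."""
    if not (0 < control_rate < 1):
        raise ValueError("control_rate must be in (0, 1)")
    if sig_count > window_len:
        raise ValueError("sig_count cannot exceed window_len")
    if sig_count < 0 or window_len < 1:
        raise ValueError("need sig_count >= 0 and window_len >= 1")
    return float(stats.binom.sf(sig_count - 1, window_len, control_rate))


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags over the candidate directed pairs."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.min() <= 0.0 or p.max() > 1.0:
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _pair_gc(
    subject_signals: list[tuple[np.ndarray, np.ndarray]],
    order: int,
    adapt_const: float,
    err_smooth: float = 0.5,
) -> np.ndarray:
    """Subject-mean GC time course from (signals, source_rows) per subject."""
    return np.mean(
        [kalman_mvar_gc(sig, src, 0, order, adapt_const, err_smooth)
         for sig, src in subject_signals],
        axis=0,
    )


def _surrogate_ensemble(
    subject_signals: list[tuple[np.ndarray, np.ndarray]],
    n_surrogates: int,
    order: int,
    adapt_const: float,
    rng: np.random.Generator,
    err_smooth: float = 0.5,
) -> np.ndarray:
    """Circular-shift surrogates of the source channels, per subject."""
    T = subject_signals[0][0].shape[1]
    out = np.empty((n_surrogates, T))
    for i in range(n_surrogates):
        per_subj = []
        for sig, src in subject_signals:
            shift = int(rng.integers(1, T))
            s2 = sig.copy()
            s2[src] = np.roll(s2[src], shift, axis=1)
            per_subj.append((s2, src))
        out[i] = _pair_gc(per_subj, order, adapt_const, err_smooth)
    return out


def directed_gc(
    epochs_by_subject: dict[int, EpochTensor],
    acc_array: np.ndarray,
    acc_times: np.ndarray,
    source_roi: int,
    target_roi: int,
    decoding_rois: list[int] | None,
    window: tuple[float, float] = (250.0, 550.0),
    order: int = 5,
    adapt_const: float = 0.02,
    downsample: int = 4,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    compress: bool = True,
    require_decoding: bool = True,
    err_smooth: float = 0.5,
) -> GCResult:
    """GCResult (without binomial/FDR fields) for one directed ROI pair.

    ``acc_array`` is (subjects, n_rois, len(acc_times)) word-trained
    accuracy; the GC index is computed per subject and averaged before
    thresholding against the surrogate ensemble.
    """
    subjects = sorted(epochs_by_subject)
    subject_signals = []
    for si, s in enumerate(subjects):
        ep = epochs_by_subject[s]
        sig, roi_ch, _ = assemble_node_signals(
            ep, acc_array[si, target_roi], acc_times, target_roi,
            decoding_rois, window, require_decoding=require_decoding,
        )
        if compress:
            sig, src_rows = compress_predictors(sig, roi_ch, source_roi)
        else:
            src_rows = roi_ch[source_roi]
        if downsample > 1:
            sig = sig[:, ::downsample]
        subject_signals.append((sig, src_rows))

    gc = _pair_gc(subject_signals, order, adapt_const, err_smooth)
    rng = np.random.default_rng([seed, source_roi, target_roi])
    surr = _surrogate_ensemble(subject_signals, n_surrogates, order,
                               adapt_const, rng, err_smooth)
    sig_mask = gc_significance(gc, surr, alpha=alpha)
    sig_mask[:order] = False            # no estimate before `order` lags
    window_len = gc.size - order
    return GCResult(
        source_roi=source_roi, target_roi=target_roi, gc_index=gc,
        sig_mask=sig_mask, window=window, sig_count=int(sig_mask.sum()),
        window_len=window_len,
    )


def run_connectivity(
    epochs_by_subject: dict[int, EpochTensor],
    acc_array: np.ndarray,
    acc_times: np.ndarray,
    decoding_rois: list[int],
    control_pair: tuple[int, int],
    window: tuple[float, float] = (250.0, 550.0),
    order: int = 5,
    adapt_const: float = 0.02,
    downsample: int = 4,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    q_fdr: float = 0.05,
    seed: int = 0,
    compress: bool = True,
    err_smooth: float = 0.5,
) -> list[GCResult]:
    """Full effective-connectivity analysis over the decoding ROI set.

    Computes the GC index for every ordered pair of decoding ROIs,
    estimates the baseline per-timepoint significance rate from the
    control pair (two uncoupled, non-decoding ROIs), tests each candidate
    count against it with an exact binomial test, and applies BH FDR over
    the k(k-1) candidate pairs.  Reciprocal pairs are flagged.
    """
    kw = dict(window=window, order=order, adapt_const=adapt_const,
              downsample=downsample, n_surrogates=n_surrogates, alpha=alpha,
              seed=seed, compress=compress, err_smooth=err_smooth)
    # control baseline: both directions of the control pair, pooled, floored
    ctrl_a = directed_gc(
        epochs_by_subject, acc_array, acc_times, control_pair[0],
        control_pair[1], decoding_rois, require_decoding=False, **kw)
    ctrl_b = directed_gc(
        epochs_by_subject, acc_array, acc_times, control_pair[1],
        control_pair[0], decoding_rois, require_decoding=False, **kw)
    control_rate = (max(ctrl_a.sig_count + ctrl_b.sig_count, 1)
                    / (2 * ctrl_a.window_len))

    results = []
    for s, t in permutations(decoding_rois, 2):
        res = directed_gc(epochs_by_subject, acc_array, acc_times, s, t,
                          decoding_rois, require_decoding=True, **kw)
        res.binomial_p = binomial_vs_control(res.sig_count, res.window_len,
                                             control_rate)
        results.append(res)

    flags = fdr_correct([r.binomial_p for r in results], q=q_fdr)
    sig_pairs = set()
    for r, f in zip(results, flags):
        r.fdr_significant = bool(f)
        if f:
            sig_pairs.add((r.source_roi, r.target_roi))
    for r in results:
        r.reciprocal = (r.fdr_significant
                        and (r.target_roi, r.source_roi) in sig_pairs)
    return results
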