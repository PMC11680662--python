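"""Synthetic multi-subject source-space epochs for the lexical-decision study.

The generator emulates what the analysis consumes — per-trial ROI-subdivision
source time courses — under an explicit additive model with three kinds of
structure:

* **Segmental signal.**  Every item is treated as a composition of three
  phoneme slots (onset, vowel, coda).  Each (ROI, neighborhood, slot) has a
  unit pattern vector over the ROI's subdivisions; a neighbor that changed
  one slot keeps the hub's patterns in the other two slots and substitutes
  an item-specific pattern in the changed one.  The per-item segmental
  pattern is the slot sum (scaled to ~unit norm), active inside the
  stimulus window.  Items that share phonological material therefore share
  pattern components, which is exactly what transfer decoding exploits.

* **Lexical signal.**  Each (ROI, neighborhood) has a unit pattern carried
  by the hub *and its word neighbors only* inside a post-offset window —
  the consolidated-wordform signature the word-trained transfer decoder is
  meant to detect.  Nonword neighbors never receive it.

* **Directed coupling.**  A coupling edge (source ROI -> target ROI,
  lag, gain) feeds the source ROI's scalar signal envelope, delayed by the
  lag, into the amplitude of the target ROI's lexical pattern.  The
  envelope carries slow stochastic amplitude modulation, so the target's
  moment-by-moment decodability genuinely depends on the source's past —
  the ground truth the Granger stage is asked to recover.

Noise is i.i.d. Gaussian per channel and timepoint (optionally AR(1)
smoothed); per-subject pattern variability is a small random rotation of
all pattern vectors; virtual talkers contribute a small additive offset
during the stimulus window.  Everything is reproducible from seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.signal import lfilter

from .design import DesignConfig, HUB_WORDS, POSITIONS, build_stimulus_set

__all__ = [
    "CouplingEdge",
    "GroundTruth",
    "EpochTensor",
    "simulate_epochs",
    "simulate_subject",
    "mark_behavioral_errors",
    "simulate_null_accuracy",
]

_LEX_IDX = {"word": 0, "nonword": 1}
_POS_IDX = {p: i for i, p in enumerate(POSITIONS)}


@dataclass(frozen=True)
class CouplingEdge:
    source_roi: int
    target_roi: int
    lag_ms: float
    gain: float


@dataclass
class GroundTruth:
    """Generative parameters; all pattern vectors are explicit and unit-norm."""

    segmental_amp: np.ndarray          # (n_rois,)
    lexical_amp: np.ndarray            # (n_rois,)
    segmental_window: tuple[float, float] = (0.0, 350.0)   # ms
    lexical_window: tuple[float, float] = (400.0, 600.0)   # ms
    noise_sd: float = 1.0
    ar1_rho: float = 0.0
    subject_jitter_sd: float = 0.05    # rad scale of per-subject pattern rotation
    talker_offset_sd: float = 0.0
    amp_mod_sd: float = 0.0            # stochastic pattern-amplitude modulation
    amp_mod_rho: float = 0.95
    coupling_edges: tuple[CouplingEdge, ...] = ()
    seed: int = 0
    # pattern banks, generated by `random`; shapes commented
    slot_patterns: np.ndarray | None = None   # (n_rois, 6, 3, S) hub slot patterns
    item_patterns: np.ndarray | None = None   # (n_rois, 6, 2, 3, S) changed-slot patterns
    lex_patterns: np.ndarray | None = None    # (n_rois, 6, S)

    @classmethod
    def random(
        cls,
        config: DesignConfig,
        segmental_rois: Sequence[int] = (),
        lexical_rois: Sequence[int] = (),
        segmental_amp: float = 1.0,
        lexical_amp: float = 1.0,
        seed: int = 0,
        **kwargs,
    ) -> "GroundTruth":
        """Draw unit pattern banks and place signal in the named ROIs."""
        R, S = config.n_rois, config.n_subdivisions
        K = len(HUB_WORDS)
        rng = np.random.default_rng(seed)

        def unit(shape):
            v = rng.normal(size=shape)
            return v / np.linalg.norm(v, axis=-1, keepdims=True)

        seg = np.zeros(R)
        seg[list(segmental_rois)] = segmental_amp
        lex = np.zeros(R)
        lex[list(lexical_rois)] = lexical_amp
        return cls(
            segmental_amp=seg,
            lexical_amp=lex,
            seed=seed,
            slot_patterns=unit((R, K, 3, S)),
            item_patterns=unit((R, K, 2, 3, S)),
            lex_patterns=unit((R, K, S)),
            **kwargs,
        )

    def validate(self, config: DesignConfig) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name, (w0, w1) in (("segmental_window", self.segmental_window),
                               ("lexical_window", self.lexical_window)):
            if not (config.epoch_start <= w0 < w1 <= config.epoch_end):
                raise ValueError(f"{name} {w0, w1} outside epoch bounds")
        if self.segmental_window[1] > config.stim_offset:
            raise ValueError("segmental_window must end by stim_offset")
        for arr, nd in ((self.slot_patterns, 4), (self.item_patterns, 5),
                        (self.lex_patterns, 3)):
            if arr is None:
                raise ValueError("pattern banks missing; build with GroundTruth.random")
            if arr.shape[0] != config.n_rois or arr.shape[-1] != config.n_subdivisions:
                raise ValueError("pattern bank shape inconsistent with config")
        for e in self.coupling_edges:
            if not np.isfinite(e.gain):
                raise ValueError("coupling gain must be finite")
            if not (0 <= e.source_roi < config.n_rois and 0 <= e.target_roi < config.n_rois):
                raise ValueError("coupling edge references unknown ROI")
        if self.segmental_amp.shape != (config.n_rois,) or \
                self.lexical_amp.shape != (config.n_rois,):
            raise ValueError("amplitude arrays must have length n_rois")


@dataclass
class EpochTensor:
    """Per-subject epochs: trials x channels x timepoints plus metadata.

    Channels are (ROI, subdivision) pairs in row-major order; the map is
    explicit in ``channel_map``.  ``trials`` aligns row-for-row with
    ``data`` and carries the schedule columns plus a ``correct`` flag.
    """

    data: np.ndarray                  # (n_trials, n_channels, n_times)
    times: np.ndarray                 # ms
    trials: pd.DataFrame
    channel_map: pd.DataFrame         # columns: channel, roi, subdivision
    subject_id: int
    baseline_corrected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.trials):
            raise ValueError("trial metadata rows must match data trials")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length mismatch")

    @property
    def n_rois(self) -> int:
        return int(self.channel_map["roi"].nunique())

    @property
    def n_subdivisions(self) -> int:
        return int(self.channel_map["subdivision"].nunique())

    def roi_slice(self, roi: int) -> slice:
        s = self.n_subdivisions
        return slice(roi * s, (roi + 1) * s)

    def copy(self, data: np.ndarray | None = None) -> "EpochTensor":
        return EpochTensor(
            data=self.data.copy() if data is None else data,
            times=self.times.copy(),
            trials=self.trials.copy(),
            channel_map=self.channel_map.copy(),
            subject_id=self.subject_id,
            baseline_corrected=self.baseline_corrected,
            normalized=self.normalized,
        )


def _channel_map(config: DesignConfig) -> pd.DataFrame:
    rois = np.repeat(np.arange(config.n_rois), config.n_subdivisions)
    subs = np.tile(np.arange(config.n_subdivisions), config.n_rois)
    return pd.DataFrame(
        {"channel": np.arange(config.n_channels), "roi": rois, "subdivision": subs}
    )


def _ar1(noise: np.ndarray, rho: float) -> np.ndarray:
    """AR(1)-filter along the last axis, preserving marginal variance."""
    if rho == 0.0:
        return noise
    return lfilter([np.sqrt(1.0 - rho ** 2)], [1.0, -rho], noise, axis=-1)


def _subject_rotation(S: int, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Small random rotation matrix: exp of a random skew-symmetric generator."""
    if jitter_sd == 0.0:
        return np.eye(S)
    A = rng.normal(scale=jitter_sd, size=(S, S))
    return expm(0.5 * (A - A.T))


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return ((times >= window[0]) & (times < window[1])).astype(float)


def simulate_subject(
    schedule: pd.DataFrame,
    truth: GroundTruth,
    config: DesignConfig,
    subject_id: int,
) -> EpochTensor:
    """Generate one subject's EpochTensor from the schedule and ground truth."""
    truth.validate(config)
    sub = schedule[schedule["subject_id"] == subject_id]
    if len(sub) == 0:
        raise ValueError(f"subject {subject_id} not in schedule")
    sub = sub.sort_values(["block_index", "trial_index_in_block"]).reset_index(drop=True)

    times = config.times
    T = times.size
    n_trials = len(sub)
    C = config.n_channels
    S = config.n_subdivisions
    rng = np.random.default_rng([truth.seed, subject_id])

    data = rng.normal(scale=truth.noise_sd, size=(n_trials, C, T))
    if truth.ar1_rho:
        data = _ar1(data, truth.ar1_rho)

    # per-subject rotation of all pattern vectors, one per ROI
    rot = np.stack([
        _subject_rotation(S, truth.subject_jitter_sd, rng)
        for _ in range(config.n_rois)
    ])

    nbhd = sub["neighborhood_id"].to_numpy()
    lex_idx = sub["lexicality"].map(_LEX_IDX).to_numpy()
    is_hub = (sub["role"] == "hub").to_numpy()
    pos = sub["changed_position"].to_numpy()
    lex_eligible = (sub["lexicality"] == "word").to_numpy()  # hub + word neighbors

    seg_mask = _window_mask(times, truth.segmental_window)
    lex_mask = _window_mask(times, truth.lexical_window)

    edges = truth.coupling_edges
    active = set(np.flatnonzero(truth.segmental_amp > 0))
    active |= set(np.flatnonzero(truth.lexical_amp > 0))
    active |= {e.source_roi for e in edges} | {e.target_roi for e in edges}

    envelopes: dict[int, np.ndarray] = {}
    for r in sorted(active):
        # per-trial pattern vectors in this ROI, rotated for this subject
        seg_pat = np.empty((n_trials, S))
        for i in range(n_trials):
            k = nbhd[i]
            slots = truth.slot_patterns[r, k].copy()  # (3, S) hub slots
            if not is_hub[i]:
                p = _POS_IDX[pos[i]]
                slots[p] = truth.item_patterns[r, k, lex_idx[i], p]
            seg_pat[i] = slots.sum(axis=0) / np.sqrt(3.0)
        seg_pat = seg_pat @ rot[r].T
        lex_pat = truth.lex_patterns[r][nbhd] @ rot[r].T   # (n_trials, S)

        # one scalar amplitude-modulation latent per ROI, common to all
        # trials of the subject: the slow gain process whose lagged echo the
        # connectivity stage is asked to recover
        if truth.amp_mod_sd > 0:
            m = _ar1(rng.normal(scale=truth.amp_mod_sd, size=T),
                     truth.amp_mod_rho)
        else:
            m = np.zeros(T)
        gain_t = 1.0 + m[None, :]
        seg_drive = truth.segmental_amp[r] * seg_mask[None, :] * gain_t
        lex_drive = (truth.lexical_amp[r] * lex_mask[None, :] * gain_t
                     * lex_eligible[:, None])
        sl = slice(r * S, (r + 1) * S)
        data[:, sl, :] += (seg_pat[:, :, None] * seg_drive[:, None, :]
                           + lex_pat[:, :, None] * lex_drive[:, None, :])
        envelopes[r] = seg_drive + lex_drive

    for e in edges:
        lag = int(round(e.lag_ms * config.sample_rate / 1000.0))
        env = envelopes[e.source_roi]
        shifted = np.zeros_like(env)
        if lag < env.shape[1]:
            shifted[:, lag:] = env[:, : env.shape[1] - lag] if lag else env
        tgt_pat = truth.lex_patterns[e.target_roi][nbhd] @ rot[e.target_roi].T
        drive = e.gain * shifted * lex_eligible[:, None]
        sl = slice(e.target_roi * S, (e.target_roi + 1) * S)
        data[:, sl, :] += tgt_pat[:, :, None] * drive[:, None, :]

    if truth.talker_offset_sd > 0:
        stim_mask = _window_mask(times, (0.0, config.stim_offset))
        offsets = rng.normal(scale=truth.talker_offset_sd,
                             size=(config.n_talkers, C))
        talker = sub["talker_id"].to_numpy()
        data += offsets[talker][:, :, None] * stim_mask[None, None, :]

    trials = sub.copy()
    trials["correct"] = True
    return EpochTensor(
        data=data, times=times, trials=trials,
        channel_map=_channel_map(config), subject_id=subject_id,
    )


def simulate_epochs(
    schedule: pd.DataFrame, truth: GroundTruth, config: DesignConfig
) -> dict[int, EpochTensor]:
    """EpochTensors for every subject in the schedule (subject id -> tensor)."""
    return {
        int(s): simulate_subject(schedule, truth, config, int(s))
        for s in sorted(schedule["subject_id"].unique())
    }


def mark_behavioral_errors(
    epochs: EpochTensor,
    error_rate_words: float,
    error_rate_nonwords: float,
    seed: int,
) -> EpochTensor:
    """Set per-trial ``correct`` flags by independent lexicality-specific draws."""
    for name, r in (("error_rate_words", error_rate_words),
                    ("error_rate_nonwords", error_rate_nonwords)):
        if not (0.0 <= r < 1.0):
            raise ValueError(f"{name} must be in [0, 1), got {r}")
    rng = np.random.default_rng([seed, epochs.subject_id])
    out = epochs.copy()
    is_word = (out.trials["lexicality"] == "word").to_numpy()
    rate = np.where(is_word, error_rate_words, error_rate_nonwords)
    out.trials["correct"] = rng.random(len(out.trials)) >= rate
    return out


def simulate_null_accuracy(
    n_subjects: int,
    n_rois: int,
    n_timepoints: int,
    seed: int,
    n_pairs: int = 15,
    n_assignments: int = 100,
    n_test_bins: int = 8,
) -> np.ndarray:
    """Zero-signal decoding-accuracy datasets for calibration studies.

    Models the accuracy measurement under the exchangeable null: each
    subject x ROI x timepoint accuracy is the mean of
    ``n_pairs * n_assignments * n_test_bins`` fair-coin test decisions,
    i.e. Binomial(n, 0.5)/n — the distribution pairwise transfer accuracy
    has when the features carry no condition information.  Returns an
    array of shape (n_subjects, n_rois, n_timepoints).
    """
    rng = np.random.default_rng(seed)
    n = n_pairs * n_assignments * n_test_bins
    draws = rng.binomial(n, 0.5, size=(n_subjects, n_rois, n_timepoints))
    return draws / float(n)
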