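"""Experimental design: stimulus neighborhoods, conditions, and trial schedules.

The lexical-decision study is built around six phonological neighborhoods.
Each neighborhood is anchored by a *hub* word (a CVC item built from stop
consonants) and six *neighbors* obtained by changing exactly one phoneme of
the hub — three real-word neighbors and three nonword neighbors, with the
changed position (onset consonant, vowel, coda consonant) counterbalanced
within each lexicality.  The changed position determines which part of the
hub's phonological frame a neighbor still shares:

========  =============  =================================
changed    overlap_class  shared material with the hub
========  =============  =================================
none       full           the whole CVC (the hub itself)
coda       shares_CV      initial consonant + vowel
vowel      shares_frame   both consonants (C_C frame)
onset      shares_VC      vowel + final consonant
========  =============  =================================

Stimuli are presented in 16 blocks of 48 trials (each hub twice, each
neighbor once per block), with two non-consecutive blocks per virtual
talker, in a pseudo-random order under the constraint that the second
presentation of a hub never directly follows its first presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HUB_WORDS",
    "POSITIONS",
    "CONDITIONS",
    "StimulusItem",
    "DesignConfig",
    "build_stimulus_set",
    "make_schedule",
    "select_training_items",
    "neighborhood_pairs",
    "schedule_violations",
]

#: Hub words anchoring the six phonological neighborhoods.
HUB_WORDS = ("pig", "toad", "cab", "bike", "dupe", "gut")

#: Changeable phoneme positions in a CVC frame.
POSITIONS = ("onset", "vowel", "coda")

#: Training-set conditions for transfer decoding.
CONDITIONS = ("words_only", "nonwords_only", "cv_overlap", "vc_overlap")

_OVERLAP_BY_POSITION = {
    "none": "full",
    "coda": "shares_CV",
    "vowel": "shares_frame",
    "onset": "shares_VC",
}


@dataclass(frozen=True)
class StimulusItem:
    """One CVC stimulus: a hub word or one of its one-phoneme neighbors."""

    label: str
    lexicality: str          # "word" | "nonword"
    neighborhood_id: int     # 0..5, index into HUB_WORDS
    role: str                # "hub" | "neighbor"
    changed_position: str    # "none" | "onset" | "vowel" | "coda"
    overlap_class: str       # "full" | "shares_CV" | "shares_frame" | "shares_VC"

    def __post_init__(self) -> None:
        if self.role not in ("hub", "neighbor"):
            raise ValueError(f"bad role {self.role!r}")
        if self.lexicality not in ("word", "nonword"):
            raise ValueError(f"bad lexicality {self.lexicality!r}")
        if (self.role == "hub") != (self.changed_position == "none"):
            raise ValueError("role=hub iff changed_position=none")
        if self.overlap_class != _OVERLAP_BY_POSITION[self.changed_position]:
            raise ValueError("overlap_class inconsistent with changed_position")
        if self.role == "hub" and self.lexicality != "word":
            raise ValueError("hubs are words")


@dataclass
class DesignConfig:
    """Study-design parameters; defaults reproduce the published design."""

    n_subjects: int = 20
    n_talkers: int = 8
    n_blocks: int = 16
    hub_reps_per_block: int = 2
    neighbor_reps_per_block: int = 1
    sample_rate: float = 1000.0       # Hz
    epoch_start: float = -100.0       # ms relative to stimulus onset
    epoch_end: float = 1000.0         # ms
    stim_offset: float = 350.0        # ms, duration-normalized stimulus end
    n_rois: int = 39
    n_subdivisions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks != 2 * self.n_talkers:
            raise ValueError("n_blocks must equal 2 * n_talkers")
        if not (self.epoch_start < 0.0 < self.stim_offset < self.epoch_end):
            raise ValueError("need epoch_start < 0 < stim_offset < epoch_end")
        for name in ("n_subjects", "n_talkers", "n_blocks", "n_rois",
                     "n_subdivisions", "hub_reps_per_block",
                     "neighbor_reps_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in ms, closed interval [epoch_start, epoch_end]."""
        step = 1000.0 / self.sample_rate
        n = int(round((self.epoch_end - self.epoch_start) / step)) + 1
        return self.epoch_start + step * np.arange(n)

    @property
    def n_timepoints(self) -> int:
        return self.times.size

    @property
    def n_channels(self) -> int:
        return self.n_rois * self.n_subdivisions

    @property
    def trials_per_block(self) -> int:
        n_hub = len(HUB_WORDS) * self.hub_reps_per_block
        n_neighbor = len(HUB_WORDS) * 6 * self.neighbor_reps_per_block
        return n_hub + n_neighbor

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def build_stimulus_set(config: DesignConfig | None = None) -> list[StimulusItem]:
    """Construct the 42-item stimulus set: 6 neighborhoods x (1 hub + 6 neighbors).

    Neighbor identities below the level of (lexicality, changed position,
    neighborhood) do not matter downstream, so neighbors carry generated
    labels of the form ``<hub>~<lexicality>-<position>``.
    """
    items: list[StimulusItem] = []
    for k, hub in enumerate(HUB_WORDS):
        items.append(StimulusItem(hub, "word", k, "hub", "none", "full"))
        for lex in ("word", "nonword"):
            for pos in POSITIONS:
                items.append(
                    StimulusItem(
                        f"{hub}~{lex}-{pos}", lex, k, "neighbor", pos,
                        _OVERLAP_BY_POSITION[pos],
                    )
                )
    return items


def select_training_items(
    items: Sequence[StimulusItem], neighborhood_id: int, condition: str
) -> list[StimulusItem]:
    """Neighbors of one neighborhood used to train a classifier.

    ``words_only`` / ``nonwords_only`` pick the three neighbors of one
    lexicality; ``cv_overlap`` / ``vc_overlap`` pick the two neighbors (one
    word, one nonword) sharing the hub's initial CV- (coda changed) or final
    -VC (onset changed).  The hub itself is never returned: it is reserved
    for the transfer test.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    pool = [
        it for it in items
        if it.neighborhood_id == neighborhood_id and it.role == "neighbor"
    ]
    if not pool:
        raise ValueError(f"no items for neighborhood {neighborhood_id}")
    if condition == "words_only":
        return [it for it in pool if it.lexicality == "word"]
    if condition == "nonwords_only":
        return [it for it in pool if it.lexicality == "nonword"]
    if condition == "cv_overlap":
        return [it for it in pool if it.changed_position == "coda"]
    return [it for it in pool if it.changed_position == "onset"]


def neighborhood_pairs(n_neighborhoods: int = 6) -> list[tuple[int, int]]:
    """All unordered hub pairs entering pairwise decoding (15 under defaults)."""
    return list(combinations(range(n_neighborhoods), 2))


def _assign_talker_blocks(n_talkers: int, rng: np.random.Generator,
                          max_tries: int = 1000) -> np.ndarray:
    """Talker id per block, two blocks each, no talker in consecutive blocks."""
    base = np.repeat(np.arange(n_talkers), 2)
    for _ in range(max_tries):
        perm = rng.permutation(base)
        if np.all(perm[1:] != perm[:-1]):
            return perm
    raise RuntimeError("could not place talker blocks non-consecutively")


def _order_block(labels: list[str], roles: list[str], rng: np.random.Generator,
                 max_tries: int = 1000) -> np.ndarray:
    """Permutation of block trials; repeated hubs never adjacent."""
    idx = np.arange(len(labels))
    for _ in range(max_tries):
        perm = rng.permutation(idx)
        ok = True
        for a, b in zip(perm[:-1], perm[1:]):
            if labels[a] == labels[b] and roles[a] == "hub":
                ok = False
                break
        if ok:
            return perm
    raise RuntimeError(
        "could not order block without adjacent hub repetitions; "
        "the design is degenerate (too few trials per block?)"
    )


def make_schedule(config: DesignConfig, seed: int) -> pd.DataFrame:
    """Blocked, pseudo-randomized trial schedule for all subjects.

    Returns a DataFrame with one row per trial and columns
    ``subject_id, block_index, talker_id, trial_index_in_block, item_label,
    neighborhood_id, lexicality, role, changed_position, overlap_class,
    presentation_number``.  Deterministic given ``(config, seed)``.
    """
    items = build_stimulus_set(config)
    hubs = [it for it in items if it.role == "hub"]
    neighbors = [it for it in items if it.role == "neighbor"]

    # block template: each hub hub_reps_per_block times, each neighbor
    # neighbor_reps_per_block times
    block_items: list[StimulusItem] = []
    block_pres: list[int] = []
    for it in hubs:
        for r in range(config.hub_reps_per_block):
            block_items.append(it)
            block_pres.append(r + 1)
    for it in neighbors:
        for r in range(config.neighbor_reps_per_block):
            block_items.append(it)
            block_pres.append(r + 1)
    labels = [it.label for it in block_items]
    roles = [it.role for it in block_items]

    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(config.n_subjects):
        talker_of_block = _assign_talker_blocks(config.n_talkers, rng)
        for block in range(config.n_blocks):
            perm = _order_block(labels, roles, rng)
            # presentation_number must follow temporal order within the block
            seen: dict[str, int] = {}
            for pos, j in enumerate(perm):
                it = block_items[j]
                seen[it.label] = seen.get(it.label, 0) + 1
                rows.append(
                    (subj, block, int(talker_of_block[block]), pos, it.label,
                     it.neighborhood_id, it.lexicality, it.role,
                     it.changed_position, it.overlap_class, seen[it.label])
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "block_index", "talker_id", "trial_index_in_block",
            "item_label", "neighborhood_id", "lexicality", "role",
            "changed_position", "overlap_class", "presentation_number",
        ],
    )
    return out


def schedule_violations(schedule: pd.DataFrame) -> int:
    """Brute-force scan counting hub-adjacency constraint violations.

    Counts consecutive same-block trial pairs in which the second
    presentation of a hub directly follows its first presentation.
    """
    n = 0
    for (_, _), blk in schedule.groupby(["subject_id", "block_index"], sort=True):
        blk = blk.sort_values("trial_index_in_block")
        lab = blk["item_label"].to_numpy()
        role = blk["role"].to_numpy()
        pres = blk["presentation_number"].to_numpy()
        for i in range(len(blk) - 1):
            if (role[i] == "hub" and lab[i] == lab[i + 1]
                    and pres[i] == 1 and pres[i + 1] == 2):
                n += 1
    return n
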