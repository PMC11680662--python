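import numpy as np
import pytest

from wordform import (DesignConfig, GroundTruth, build_stimulus_set,
                      make_schedule, simulate_subject)


@pytest.fixture(scope="session")
def config():
    """Desk-scale design: 3 subjects, 2 ROIs, full trial structure."""
    return DesignConfig(n_subjects=3, n_rois=2)


@pytest.fixture(scope="session")
def items(config):
    return build_stimulus_set(config)


@pytest.fixture(scope="session")
def schedule(config):
    return make_schedule(config, seed=0)


@pytest.fixture(scope="session")
def noise_truth(config):
    """Zero-amplitude ground truth: pure noise epochs."""
    return GroundTruth.random(config, seed=11)


@pytest.fixture(scope="session")
def noise_epochs(schedule, noise_truth, config):
    return simulate_subject(schedule, noise_truth, config, subject_id=0)


@pytest.fixture(scope="session")
def lexical_truth(config):
    """Strong lexical signal in ROI 0 at 400-600 ms; ROI 1 stays noise."""
    return GroundTruth.random(
        config, lexical_rois=[0], lexical_amp=2.0, lexical_window=(400.0, 600.0),
        seed=21,
    )


@pytest.fixture(scope="session")
def lexical_epochs(schedule, lexical_truth, config):
    return simulate_subject(schedule, lexical_truth, config, subject_id=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_gc_system(T, n_subj, seed, k=3, lag=5, gain=1.5, tgt_noise=1.0,
                   coupled=True):
    """Node-signal system for connectivity studies: k decoding 'ROIs' plus
    two control ROIs, each with a smooth AR(1) amplitude latent per subject.

    If ``coupled``, ROI 0's latent drives ROI 1's target channel at
    ``lag`` samples with the given gain.  ``node_signals(s, t)`` assembles,
    per subject, the channels the pipeline would hand to the Kalman stage:
    target accuracy-like channel (0), the source ROI's 8 pattern channels,
    and 3 conditioning channels, all z-scored.
    """
    r = np.random.default_rng(seed)
    lat = {}
    for roi in range(k + 2):
        m = r.normal(size=(n_subj, T + lag))
        for t in range(1, T + lag):
            m[:, t] = 0.66 * m[:, t - 1] + 0.75 * m[:, t]
        lat[roi] = m
    pats = {roi: r.normal(size=(n_subj, 8)) for roi in range(k + 2)}

    def node_signals(s_roi, t_roi):
        out = []
        for s in range(n_subj):
            tgt = lat[t_roi][s, lag:].copy()
            if coupled and t_roi == 1:
                tgt = tgt + gain * lat[0][s, :T]
            tgt = tgt + tgt_noise * np.random.default_rng(
                [seed, s, t_roi]).normal(size=T)
            p = pats[s_roi][s] / np.linalg.norm(pats[s_roi][s])
            src = (p[:, None] * lat[s_roi][s, lag:][None, :]
                   + 0.3 * np.random.default_rng([seed, s, s_roi, 9]).normal(size=(8, T)))
            cond = np.random.default_rng([seed, s, s_roi, t_roi, 3]).normal(size=(3, T))
            sig = np.vstack([tgt, src, cond])
            sig = (sig - sig.mean(1, keepdims=True)) / sig.std(1, keepdims=True)
            out.append((sig, np.arange(1, 9)))
        return out

    return node_signals
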