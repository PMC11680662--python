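"""Granger-causality machinery: assembly, Kalman filter, surrogates, tests."""

import math

import numpy as np
import pandas as pd
import pytest

from wordform.connectivity import (assemble_node_signals, binomial_vs_control,
                                   compress_predictors, fdr_correct,
                                   gc_significance, kalman_mvar_gc)
from wordform.synth import EpochTensor


def _fake_epochs(n_rois, n_trials=6, t0=-100, t1=700, seed=0):
    rng = np.random.default_rng(seed)
    times = np.arange(t0, t1 + 1, dtype=float)
    C = n_rois * 8
    data = rng.normal(size=(n_trials, C, times.size))
    trials = pd.DataFrame({"item_label": [f"t{i}" for i in range(n_trials)],
                           "correct": [True] * n_trials})
    chmap = pd.DataFrame({"channel": np.arange(C),
                          "roi": np.repeat(np.arange(n_rois), 8),
                          "subdivision": np.tile(np.arange(8), n_rois)})
    return EpochTensor(data=data, times=times, trials=trials,
                       channel_map=chmap, subject_id=0,
                       baseline_corrected=True, normalized=True)


def _ar1(rng, T, rho=0.66, scale=0.75):
    x = rng.normal(size=T)
    for t in range(1, T):
        x[t] = rho * x[t - 1] + scale * x[t]
    return x


def _coupled_nodes(T, lag=5, gain=0.8, seed=0, coupled=True):
    """Target accuracy-like channel driven by a source ROI's 8-channel
    pattern amplitude at a fixed lag, plus conditioning channels."""
    rng = np.random.default_rng(seed)
    m = _ar1(rng, T + lag)
    pat = rng.normal(size=8)
    pat /= np.linalg.norm(pat)
    src = pat[:, None] * m[None, lag:] + 0.3 * rng.normal(size=(8, T))
    tgt = (gain * m[:T] if coupled else np.zeros(T)) + rng.normal(size=T)
    cond = rng.normal(size=(3, T))
    sig = np.vstack([tgt, src, cond])
    sig = (sig - sig.mean(1, keepdims=True)) / sig.std(1, keepdims=True)
    return sig


def _reversed_nodes(T, lag=5, gain=0.8, seed=0):
    """Same system, roles swapped: source channels now carry the DRIVEN
    signal, target carries the driver."""
    rng = np.random.default_rng(seed)
    m = _ar1(rng, T + lag)
    pat = rng.normal(size=8)
    pat /= np.linalg.norm(pat)
    driven = gain * m[:T] + rng.normal(size=T)
    src = pat[:, None] * driven[None, :] + 0.3 * rng.normal(size=(8, T))
    tgt = m[lag:] + rng.normal(size=T)
    cond = rng.normal(size=(3, T))
    sig = np.vstack([tgt, src, cond])
    sig = (sig - sig.mean(1, keepdims=True)) / sig.std(1, keepdims=True)
    return sig


def _ols_gc(sig, src_rows, order=5):
    """Independent oracle: stationary OLS-VAR restricted/full log variance
    ratio for the target equation (channel 0)."""
    C, T = sig.shape
    y = sig[0, order:]

    def resid_var(rows):
        X = [np.ones(T - order)]
        for lag in range(1, order + 1):
            for c in rows:
                X.append(sig[c, order - lag:T - lag])
        X = np.column_stack(X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r / len(r)

    full = resid_var(range(C))
    red = resid_var([c for c in range(C) if c not in set(src_rows)])
    return math.log(red / full)


class TestAssembly:
    def test_model_dimension_substitution(self):
        """One target ROI substituted by its accuracy channel: the model has
        (n_rois - 1) * 8 + 1 channels."""
        for n_rois in (5, 39):
            ep = _fake_epochs(n_rois, n_trials=4, seed=n_rois)
            acc = np.full(ep.times.size, 0.6)
            acc += np.linspace(0, 0.1, acc.size)
            sig, roi_ch, tw = assemble_node_signals(
                ep, acc, ep.times, target_roi=0, decoding_rois=[0, 1])
            assert sig.shape[0] == (n_rois - 1) * 8 + 1
            assert len(roi_ch) == n_rois - 1

    def test_window_sample_count(self):
        ep = _fake_epochs(2, t1=1000)
        acc = np.linspace(0.4, 0.6, ep.times.size)
        sig, _, tw = assemble_node_signals(ep, acc, ep.times, 0, [0],
                                           window=(250.0, 550.0))
        assert tw.size == 301  # inclusive 250..550 at 1 kHz

    def test_zscored(self):
        ep = _fake_epochs(3)
        acc = np.random.default_rng(0).random(ep.times.size)
        sig, _, _ = assemble_node_signals(ep, acc, ep.times, 1, [1])
        assert np.abs(sig.mean(axis=1)).max() < 1e-9
        assert np.abs(sig.std(axis=1) - 1.0).max() < 1e-9

    def test_target_must_decode(self):
        ep = _fake_epochs(3)
        acc = np.full(ep.times.size, 0.5)
        with pytest.raises(ValueError, match="decoding ROI set"):
            assemble_node_signals(ep, acc, ep.times, 2, decoding_rois=[0, 1])

    def test_compression_keeps_source_block(self):
        ep = _fake_epochs(5)
        acc = np.random.default_rng(1).random(ep.times.size)
        sig, roi_ch, _ = assemble_node_signals(ep, acc, ep.times, 0, [0])
        comp, src_rows = compress_predictors(sig, roi_ch, source_roi=2)
        # 1 target + 8 source + 3 compressed ROIs
        assert comp.shape[0] == 1 + 8 + 3
        np.testing.assert_array_equal(src_rows, np.arange(1, 9))


class TestKalmanGC:
    def test_null_gc_small_relative_to_coupled(self):
        """Uncoupled GC carries only the finite-sample overfitting bias of
        the higher-dimensional full model (absorbed downstream by the
        surrogate calibration); coupled GC clearly exceeds it."""
        null_m, coup_m = [], []
        for rep in range(6):
            null_m.append(kalman_mvar_gc(
                _coupled_nodes(300, seed=rep, coupled=False),
                np.arange(1, 9), order=5)[5:].mean())
            coup_m.append(kalman_mvar_gc(
                _coupled_nodes(300, seed=rep, coupled=True),
                np.arange(1, 9), order=5)[5:].mean())
        assert np.mean(null_m) < 0.3
        assert np.mean(coup_m) > 1.5 * np.mean(null_m)

    def test_direction_recovery_vs_ols_oracle(self):
        """Coupled direction beats the reverse, and the ranking agrees with
        a stationary OLS-VAR oracle, in every run."""
        wins_kalman = wins_ols = 0
        runs = 12
        for rep in range(runs):
            fwd = _coupled_nodes(300, seed=rep)
            rev = _reversed_nodes(300, seed=rep)
            gf = kalman_mvar_gc(fwd, np.arange(1, 9), order=5)[5:].mean()
            gr = kalman_mvar_gc(rev, np.arange(1, 9), order=5)[5:].mean()
            wins_kalman += gf > gr
            wins_ols += _ols_gc(fwd, range(1, 9)) > _ols_gc(rev, range(1, 9))
        assert wins_kalman >= 0.9 * runs
        assert wins_ols >= 0.9 * runs
        # the two routes agree on the conclusion
        assert (wins_kalman >= 0.9 * runs) == (wins_ols >= 0.9 * runs)

    def test_deterministic(self):
        sig = _coupled_nodes(200, seed=5)
        a = kalman_mvar_gc(sig, np.arange(1, 9))
        b = kalman_mvar_gc(sig, np.arange(1, 9))
        np.testing.assert_array_equal(a, b)

    def test_nonnegative(self):
        sig = _coupled_nodes(200, seed=6)
        assert kalman_mvar_gc(sig, np.arange(1, 9)).min() >= 0.0

    def test_nonfinite_rejected(self):
        sig = _coupled_nodes(100, seed=0)
        sig[0, 10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            kalman_mvar_gc(sig, np.arange(1, 9))

    def test_order_too_large(self):
        sig = _coupled_nodes(20, seed=0)
        with pytest.raises(ValueError, match="too short"):
            kalman_mvar_gc(sig, np.arange(1, 9), order=30)


class TestGCSignificance:
    def test_observed_above_all_surrogates(self, rng):
        gc = np.full(50, 2.0)
        surr = rng.random((120, 50))
        assert gc_significance(gc, surr).all()

    def test_alpha_one_all_true(self, rng):
        gc = rng.random(30)
        assert gc_significance(gc, rng.random((150, 30)), alpha=1.0).all()

    def test_too_few_surrogates(self, rng):
        with pytest.raises(ValueError, match="surrogate"):
            gc_significance(np.zeros(10), rng.random((50, 10)))

    def test_null_exceedance_rate_near_alpha(self):
        """Exceedance of the 95% surrogate quantile on exchangeable null
        data: mean rate within 3 SE of alpha across repeats."""
        from wordform.connectivity import _pair_gc, _surrogate_ensemble
        rates = []
        for rep in range(8):
            ss = [( _coupled_nodes(76, seed=100 * rep + s, coupled=False),
                    np.arange(1, 9)) for s in range(4)]
            gc = _pair_gc(ss, 5, 0.02)
            surr = _surrogate_ensemble(ss, 100, 5, 0.02,
                                       np.random.default_rng(rep))
            mask = gc_significance(gc, surr)
            rates.append(mask[5:].mean())
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 0.05) < 3 * se + 0.01


class TestBinomial:
    def test_zero_count_p_one(self):
        assert binomial_vs_control(0, 301, 0.05) == 1.0

    def test_direct_summation_oracle(self):
        n, rate, k = 301, 15 / 301, 60
        p = binomial_vs_control(k, n, rate)
        direct = sum(math.comb(n, j) * rate ** j * (1 - rate) ** (n - j)
                     for j in range(k, n + 1))
        assert p == pytest.approx(direct, rel=1e-10)

    def test_saturated_count_tiny_p(self):
        p = binomial_vs_control(301, 301, 0.05)
        assert p == pytest.approx(0.05 ** 301, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_vs_control(10, 5, 0.05)
        with pytest.raises(ValueError):
            binomial_vs_control(3, 10, 0.0)


class TestFDR:
    def test_all_small_all_significant(self):
        assert fdr_correct([0.001] * 20, q=0.05).all()

    def test_hand_computed_bh(self):
        # BH thresholds at q=0.05 for m=3: 0.0167, 0.0333, 0.05
        flags = fdr_correct([0.001, 0.2, 0.9], q=0.05)
        assert flags.tolist() == [True, False, False]

    def test_empty(self):
        assert fdr_correct([], q=0.05).size == 0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            fdr_correct([0.0, 0.1])
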