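"""Sign-flip cluster permutation inference: oracles, calibration, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wordform.cluster import (between_condition_clusters, bonferroni_gate,
                              cluster_p_value, find_clusters, max_run_lengths,
                              permutation_null_single, pointwise_above_chance,
                              single_condition_clusters)
from wordform.synth import simulate_null_accuracy


class TestPointwise:
    def test_constant_chance_empty(self):
        acc = np.full((20, 50), 0.5)
        assert not pointwise_above_chance(acc).any()

    def test_strong_effect_localized(self, rng):
        """Closed-form check: 20 subjects at 0.75 with tiny jitter are
        significant exactly where the effect is (exact chance elsewhere has
        zero deviation, hence t = 0)."""
        acc = np.full((20, 300), 0.5)
        acc[:, 100:201] = 0.75 + rng.normal(0, 1e-4, (20, 101))
        mask = pointwise_above_chance(acc)
        assert mask[100:201].all()
        assert not mask[:100].any() and not mask[201:].any()

    def test_below_chance_one_tailed(self, rng):
        acc = 0.4 + rng.normal(0, 1e-3, (10, 40))
        assert not pointwise_above_chance(acc).any()

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            pointwise_above_chance(np.full((1, 10), 0.6))


class TestFindClusters:
    def test_known_runs(self):
        mask = np.zeros(50, dtype=bool)
        mask[10:21] = True
        mask[40:42] = True
        assert find_clusters(mask) == [(10, 20, 11), (40, 41, 2)]

    def test_all_false(self):
        assert find_clusters(np.zeros(30, dtype=bool)) == []

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    def test_exhaustive_scan_oracle(self, bits):
        mask = np.array(bits, dtype=bool)
        clusters = find_clusters(mask)
        # brute force: scan every index, grow runs
        brute = []
        start = None
        for i, v in enumerate(mask):
            if v and start is None:
                start = i
            if not v and start is not None:
                brute.append((start, i - 1, i - start))
                start = None
        if start is not None:
            brute.append((start, len(mask) - 1, len(mask) - start))
        assert clusters == brute
        if clusters:
            assert max_run_lengths(mask[None, :])[0] == max(c[2] for c in clusters)
        else:
            assert max_run_lengths(mask[None, :])[0] == 0


class TestPermutationNull:
    def test_deterministic(self, rng):
        acc = 0.5 + rng.normal(0, 0.02, (8, 200))
        a = permutation_null_single(acc, n_perm=100, seed=5)
        b = permutation_null_single(acc, n_perm=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_exchangeability_lower_bound(self, rng):
        """Observed statistic inserted into its own null: p >= 1/(n_perm+1)."""
        acc = 0.5 + rng.normal(0, 0.02, (8, 200))
        null = permutation_null_single(acc, n_perm=100, seed=5)
        obs = max_run_lengths(pointwise_above_chance(acc)[None, :])[0]
        assert cluster_p_value(int(obs), null) >= 1 / 101

    def test_strong_effect_minimal_p(self, rng):
        """A sustained moderate effect across 20 subjects reaches the
        smallest attainable permutation p-value."""
        acc = simulate_null_accuracy(20, 1, 400, seed=3)[:, 0, :]
        acc[:, 100:250] += 0.015
        recs = single_condition_clusters(acc, np.arange(400), n_perm=400, seed=1)
        big = max(recs, key=lambda r: r.size)
        assert big.p_value <= 6 / 401
        assert big.size >= 140

    def test_monotone_in_effect_size(self):
        """Larger injected effects never shrink the largest cluster
        (matched noise)."""
        base = simulate_null_accuracy(10, 1, 300, seed=7)[:, 0, :]
        sizes = []
        for amp in (0.0, 0.02, 0.05, 0.1):
            acc = base.copy()
            acc[:, 100:200] += amp
            obs = max_run_lengths(pointwise_above_chance(acc)[None, :])[0]
            sizes.append(int(obs))
        assert sizes == sorted(sizes)

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError):
            permutation_null_single(np.full((4, 10), 0.5), n_perm=0, seed=0)


class TestBonferroni:
    def test_printed_threshold(self):
        # 0.05 / 39 = 0.00128 (to printed precision)
        assert round(0.05 / 39, 5) == 0.00128
        assert bonferroni_gate(np.array([0.001]), n_rois=39)[0]
        assert not bonferroni_gate(np.array([0.0013]), n_rois=39)[0]

    def test_single_roi_reduces_to_alpha(self):
        flags = bonferroni_gate(np.array([0.049, 0.051]), n_rois=1)
        assert flags.tolist() == [True, False]

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni_gate(np.array([0.0]))


class TestBetweenConditions:
    def test_identical_conditions_no_clusters(self, rng):
        acc = 0.5 + rng.normal(0, 0.02, (10, 150))
        a, b = between_condition_clusters(acc, acc.copy(), np.arange(150),
                                          n_perm=50, seed=0)
        assert a == [] and b == []

    def test_word_effect_recovered_directionally(self):
        """Condition A above chance and above B in 400-600 ms yields an A>B
        cluster there and no B>A clusters."""
        accs = simulate_null_accuracy(12, 2, 500, seed=11)
        a, b = accs[:, 0, :], accs[:, 1, :]
        a[:, 200:350] += 0.06
        times = np.arange(500)
        rec_ab, rec_ba = between_condition_clusters(a, b, times, n_perm=200,
                                                    seed=4)
        big = max(rec_ab, key=lambda r: r.size)
        assert big.start_ms <= 215 and big.end_ms >= 335
        assert big.p_value < 0.05
        assert all(r.size < 10 for r in rec_ba)

    def test_shared_signal_suppressed(self):
        """Both conditions equally above chance: the difference constraint
        blocks cluster formation."""
        accs = simulate_null_accuracy(12, 2, 500, seed=13)
        a, b = accs[:, 0, :], accs[:, 1, :]
        a[:, 200:350] += 0.06
        b[:, 200:350] += 0.06
        rec_ab, rec_ba = between_condition_clusters(a, b, np.arange(500),
                                                    n_perm=200, seed=4)
        assert all(r.size < 10 for r in rec_ab + rec_ba)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="matching shapes"):
            between_condition_clusters(np.zeros((4, 10)), np.zeros((4, 12)),
                                       np.arange(10), n_perm=10, seed=0)


class TestFamilywiseCalibration:
    def test_fwer_on_null_simulations(self):
        """Zero-signal datasets, 5-ROI family: fraction with any
        Bonferroni-significant cluster stays near/below the nominal level."""
        n_datasets, n_rois, alpha = 60, 5, 0.05
        hits = 0
        for d in range(n_datasets):
            accs = simulate_null_accuracy(8, n_rois, 300, seed=1000 + d)
            sig = False
            for r in range(n_rois):
                recs = single_condition_clusters(
                    accs[:, r, :], np.arange(300), n_perm=200, seed=17 + d)
                ps = [rec.p_value for rec in recs]
                if ps and bonferroni_gate(ps, n_rois=n_rois).any():
                    sig = True
            hits += sig
        mc_se = np.sqrt(alpha * (1 - alpha) / n_datasets)
        assert hits / n_datasets <= alpha + 2 * mc_se
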