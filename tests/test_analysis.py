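"""Analysis layer: rate curves, replay scoring, transitions, speed, PSPs.

Most expected values come from constructed spike data with known ground
truth; the replay metrics are additionally checked against brute-force
computations on the same data.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lifsorn.analysis import (
    IsiStats,
    cluster_cross_correlogram,
    first_peak,
    firing_time,
    forward_backward_transition_change,
    isi_stats,
    match_persistence,
    normalize_correlograms,
    pairwise_correlation,
    rate_curve,
    recall_speed,
    replay_trials,
    shift_test,
    spearman_replay,
    transition_probabilities,
    trial_rhos,
    weight_to_psp,
)
from lifsorn.fixtures import scripted_sequence_spikes, uniform_cluster_positions
from lifsorn.protocol import build_clusters


@pytest.fixture(scope="module")
def clusters():
    pos, x0, y = uniform_cluster_positions(per_cluster=5, seed=1)
    return build_clusters((375.0, 500.0), (2125.0, 500.0), 8, 100.0, pos)


class TestPairwiseCorrelation:
    def test_identical_trains(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 10_000, 300))
        times = np.r_[t, t]
        ids = np.r_[np.zeros(300, int), np.ones(300, int)]
        c = pairwise_correlation(times, ids, 2, 0, 10_000, 20.0)
        assert c[0] == pytest.approx(1.0)

    def test_independent_poisson_centered_at_zero(self):
        rng = np.random.default_rng(1)
        n, dur = 40, 100_000.0
        times, ids = [], []
        for i in range(n):
            t = np.sort(rng.uniform(0, dur, int(3e-3 * dur)))
            times.append(t)
            ids.append(np.full(len(t), i))
        times = np.concatenate(times)
        ids = np.concatenate(ids)
        c = pairwise_correlation(times, ids, n, 0, dur, 20.0)
        se = c.std() / np.sqrt(len(c))
        assert abs(c.mean()) < 3 * max(se, 1e-4)

    def test_width_grows_with_bin(self):
        rng = np.random.default_rng(2)
        # two anti-phase oscillating rates make correlations bin-dependent
        times, ids = [], []
        for i in range(20):
            t = np.sort(rng.uniform(0, 50_000, 200))
            times.append(t)
            ids.append(np.full(200, i))
        times = np.concatenate(times)
        ids = np.concatenate(ids)
        c20 = pairwise_correlation(times, ids, 20, 0, 50_000, 20.0)
        c200 = pairwise_correlation(times, ids, 20, 0, 50_000, 200.0)
        assert abs(c200.mean()) < 0.05 and abs(c20.mean()) < 0.05
        assert c200.std() > c20.std()

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlation(np.array([1.0]), np.array([0]), 1, 0, 1.0, 20.0)


class TestIsiStats:
    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.exponential(100.0, 5000))
        s = isi_stats(t, np.zeros(len(t), int), [0])
        assert s.cvs[0] == pytest.approx(1.0, abs=0.08)

    def test_periodic_cv_zero(self):
        t = np.arange(0, 10_000, 250.0)
        s = isi_stats(t, np.zeros(len(t), int), [0])
        assert s.cvs[0] == pytest.approx(0.0, abs=1e-12)

    def test_dead_time_depresses_cv(self):
        # Poisson with 5 ms dead time at ~3 Hz: CV slightly below 1,
        # matching a brute-force simulation of the thinned process
        rng = np.random.default_rng(1)
        isi = rng.exponential(1000.0 / 3.0, 30_000) + 5.0
        t = np.cumsum(isi)
        s = isi_stats(t, np.zeros(len(t), int), [0])
        expected_cv = (1000.0 / 3.0) / (1000.0 / 3.0 + 5.0)
        assert s.cvs[0] == pytest.approx(expected_cv, abs=0.02)
        assert s.cvs[0] < 1.0

    def test_exponential_tail_fit(self):
        rng = np.random.default_rng(2)
        isi = rng.exponential(250.0, 50_000)
        t = np.cumsum(isi)
        s = isi_stats(t, np.zeros(len(t), int), [0])
        assert 1.0 / s.fit_rate == pytest.approx(250.0, rel=0.05)

    def test_single_spike_skipped(self):
        s = isi_stats(np.array([5.0]), np.array([0]), [0])
        assert len(s.cvs) == 0


class TestRateCurve:
    def test_kernel_mass_conservation(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(400, 600, 57)
        grid, rate = rate_curve(t, 0.0, 1000.0, 1.0, 50.0)
        assert np.sum(rate) * 1e-3 == pytest.approx(57.0, rel=1e-6)

    def test_nonnegative(self):
        grid, rate = rate_curve(np.array([100.0]), 0, 300, 1.0, 50.0)
        assert np.all(rate >= 0)

    def test_single_burst_peak_location(self):
        t = np.full(30, 120.0)
        ft = firing_time(t, 0.0, 500.0)
        assert ft == pytest.approx(120.0, abs=1.0)

    def test_first_of_two_bursts(self):
        t = np.r_[np.full(20, 100.0), np.full(20, 300.0)]
        assert firing_time(t, 0.0, 500.0) == pytest.approx(100.0, abs=1.0)

    def test_empty_is_missing(self):
        assert firing_time(np.empty(0), 0.0) is None

    def test_plateau_midpoint(self):
        rate = np.array([0.0, 1, 2, 2, 2, 1, 0])
        grid = np.arange(7.0)
        assert first_peak(grid, rate) == pytest.approx(3.0)

    def test_monotone_has_no_peak(self):
        assert first_peak(np.arange(5.0), np.arange(5.0)) is None


class TestSpearman:
    def test_perfect_orders(self):
        pos = np.arange(8.0)
        assert spearman_replay(list(np.arange(8.0)), pos) == pytest.approx(1.0)
        assert spearman_replay(list(np.arange(8.0)[::-1]), pos) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        # times (10,20,30,40) at positions (1,2,4,3): rho = 0.8
        assert spearman_replay([10, 20, 30, 40], np.array([1, 2, 4, 3])) == pytest.approx(0.8)

    def test_missing_dropped(self):
        rho = spearman_replay([None, 1.0, 2.0, None, 3.0], np.array([9, 1, 2, 9, 3]))
        assert rho == pytest.approx(1.0)

    def test_fewer_than_two_is_nan(self):
        assert np.isnan(spearman_replay([None, 5.0], np.array([1, 2])))

    def test_matches_scipy_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ft = rng.uniform(0, 500, 8)
            pos = np.arange(8.0)
            assert spearman_replay(list(ft), pos) == pytest.approx(
                stats.spearmanr(ft, pos).statistic
            )


class TestShiftTest:
    def test_identical_samples(self):
        a = np.array([0.1, 0.2, 0.3])
        d, ks, p = shift_test(a, a.copy())
        assert d == 0.0 and ks == 0.0

    def test_location_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, 300)
        d, ks, p = shift_test(a, a + 0.5)
        assert d == pytest.approx(0.5, abs=1e-9)
        assert p < 1e-6

    def test_null_pvalue_roughly_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            ps.append(shift_test(rng.normal(size=60), rng.normal(size=60))[2])
        ps = np.array(ps)
        assert 0.3 < np.mean(ps < 0.5) < 0.7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shift_test(np.empty(0), np.array([1.0]))


class TestScriptedReplay:
    def test_forward_script_scores_one(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 60.0)
        trials = replay_trials(spikes, clusters, onsets, "test1")
        rhos = trial_rhos(trials)
        np.testing.assert_allclose(rhos, 1.0)

    def test_reversed_script_scores_minus_one(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(7, -1, -1), 60.0)
        trials = replay_trials(spikes, clusters, onsets, "test1")
        np.testing.assert_allclose(trial_rhos(trials), -1.0)

    def test_shuffled_orders_center_at_zero(self, clusters):
        rng = np.random.default_rng(0)
        rhos = []
        for k in range(40):
            order = rng.permutation(8)
            spikes, onsets = scripted_sequence_spikes(
                clusters, order, 60.0, n_trials=1, seed=k
            )
            rhos.extend(trial_rhos(replay_trials(spikes, clusters, onsets, "test1")))
        rhos = np.asarray(rhos)
        assert abs(rhos.mean()) < 3 * rhos.std() / np.sqrt(len(rhos))

    def test_reverse_axis_flips_sign(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 60.0)
        trials = replay_trials(spikes, clusters, onsets, "test1", reverse_axis=True)
        np.testing.assert_allclose(trial_rhos(trials), -1.0)

    def test_recall_speed_ground_truth(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 60.0)
        trials = replay_trials(spikes, clusters, onsets, "test1")
        df = recall_speed(trials, clusters.axis_positions)
        spacing = np.diff(clusters.axis_positions).mean()
        np.testing.assert_allclose(df["speed_um_per_ms"], spacing / 60.0, rtol=1e-6)

    def test_recall_speed_noisy_recovery(self, clusters):
        rng = np.random.default_rng(5)
        slopes = []
        for k in range(10):
            spikes, onsets = scripted_sequence_spikes(
                clusters, range(8), 60.0, jitter_ms=5.0, n_trials=5, seed=k
            )
            trials = replay_trials(spikes, clusters, onsets, "test1")
            df = recall_speed(trials, clusters.axis_positions)
            slopes.extend(df["speed_um_per_ms"])
        spacing = np.diff(clusters.axis_positions).mean()
        assert np.mean(slopes) == pytest.approx(spacing / 60.0, rel=0.15)

    def test_equal_times_rejected(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 60.0)
        # collapse all bursts to the same time: rho undefined or <= 0.9
        spikes["time_ms"] = (spikes["time_ms"] // 2000) * 2000 + 100.0
        trials = replay_trials(spikes, clusters, onsets, "test1")
        df = recall_speed(trials, clusters.axis_positions)
        assert len(df) == 0


class TestCrossCorrelogram:
    def test_shifted_train_peak_at_lag(self, clusters):
        # cluster B spikes = cluster A spikes shifted +50 ms
        rng = np.random.default_rng(0)
        base = np.sort(rng.uniform(10, 400, 40))
        rows = []
        for nid in clusters.members[0]:
            rows += [(t, nid) for t in base]
        for nid in clusters.members[1]:
            rows += [(t + 50.0, nid) for t in base]
        spikes = pd.DataFrame(
            {
                "time_ms": [r[0] for r in rows],
                "neuron_id": [r[1] for r in rows],
                "phase": "test1",
                "trial": 0,
            }
        )
        cc = cluster_cross_correlogram(spikes, clusters, np.array([0.0]), "test1")
        lags = np.arange(-25, 26) * 10.0
        assert lags[np.argmax(cc[1])] == pytest.approx(50.0)

    def test_sequential_bursts_mass_at_positive_lags(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 60.0)
        cc = cluster_cross_correlogram(spikes, clusters, onsets, "test1")
        lags = np.arange(-25, 26) * 10.0
        for d in (1, 2, 3):
            assert lags[np.argmax(cc[d])] == pytest.approx(60.0 * d, abs=10.0)
        # brute-force double loop on one pair
        sub = spikes[spikes["trial"] == 0]
        a = sub[sub["neuron_id"].isin(clusters.members[0])]["time_ms"].to_numpy()
        b = sub[sub["neuron_id"].isin(clusters.members[1])]["time_ms"].to_numpy()
        onset = onsets[0]
        binned = lambda t: np.bincount(((t - onset) // 10).astype(int), minlength=50)[:50]
        xa, xb = binned(a), binned(b)
        brute = np.array(
            [np.sum(xa[max(0, -l): 50 - max(0, l)] * xb[max(0, l): 50 + min(0, l)])
             for l in range(-25, 26)]
        )
        one_trial = cluster_cross_correlogram(
            spikes[spikes["trial"] == 0], clusters, onsets[:1], "test1"
        )
        # the 0->1 pair contributes 'brute' to the distance-1 group
        assert np.argmax(one_trial[1][15:36]) == np.argmax(brute[15:36])

    def test_normalization_to_unit_interval(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 60.0)
        cc = normalize_correlograms(
            cluster_cross_correlogram(spikes, clusters, onsets, "test1")
        )
        for v in cc.values():
            assert v.min() >= 0.0 and v.max() <= 1.0


class TestTransitions:
    def test_alternating_sequence(self, clusters):
        # bursts A,B,A,B...: P(A->B) = 1 and P(B->A) = 1
        rows = []
        for k in range(10):
            for j, c in enumerate([0, 1]):
                t = 1000.0 * k + 300.0 * j + 100.0
                for nid in clusters.members[c]:
                    rows.append((t, nid))
        spikes = pd.DataFrame(
            {
                "time_ms": [r[0] for r in rows],
                "neuron_id": [r[1] for r in rows],
                "phase": "test1",
                "trial": -1,
            }
        )
        m = transition_probabilities(spikes, clusters, "test1", 0.0, 10_000.0)
        assert m[0, 1] == pytest.approx(1.0)
        assert m[1, 0] == pytest.approx(1.0)
        assert np.isnan(m[2]).all()

    def test_rows_sum_to_one(self, clusters):
        spikes, onsets = scripted_sequence_spikes(
            clusters, range(8), 120.0, n_trials=6
        )
        m = transition_probabilities(
            spikes, clusters, "test1", 0.0, float(spikes["time_ms"].max() + 500)
        )
        sums = np.nansum(m, axis=1)
        for i in range(8):
            if not np.isnan(m[i]).all():
                assert sums[i] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, clusters):
        spikes, onsets = scripted_sequence_spikes(clusters, range(8), 120.0, n_trials=4)
        m = transition_probabilities(
            spikes, clusters, "test1", 0.0, float(spikes["time_ms"].max() + 500)
        )
        # constructed sequence: A..H repeated 4 times -> A->B prob 1, H->A prob 1
        assert m[0, 1] == pytest.approx(1.0)
        assert m[7, 0] == pytest.approx(1.0)

    def test_forward_backward_change(self):
        before = np.zeros((8, 8))
        after = np.zeros((8, 8))
        after[0, 1] = after[1, 2] = 0.3
        after[2, 1] = -0.0
        fwd, bwd = forward_backward_transition_change(before, after)
        assert fwd > 0 and bwd == 0.0


class TestMatchPersistence:
    def test_identical_pre_post_zero_change(self):
        # every bin holds the same mix of matches as the pre-training phase
        rho = np.array([0.7, 0.2] * 4)
        t = np.repeat(np.arange(4) * 60.0, 2) + np.tile([10.0, 40.0], 4)
        df = match_persistence(rho, rho, t, bin_s=60.0)
        np.testing.assert_allclose(df["change_pct"], 0.0)

    def test_full_contrast(self):
        df = match_persistence(
            np.zeros(10), np.ones(10), np.linspace(0, 50, 10), bin_s=60.0
        )
        assert df["change_pct"].iloc[0] == pytest.approx(100.0)

    def test_decay_by_counting(self):
        # scripted decay: matches vanish after 300 s
        rng = np.random.default_rng(0)
        t = np.arange(0, 360, 2.0)
        rho = np.where(t < 300, 1.0, 0.0)
        df = match_persistence(np.zeros(50), rho, t, bin_s=60.0)
        np.testing.assert_allclose(df["change_pct"].iloc[:5], 100.0)
        assert df["change_pct"].iloc[5] == pytest.approx(0.0)


class TestWeightToPsp:
    def test_zero_weight(self):
        assert weight_to_psp(0.0, "EE") == 0.0

    def test_closed_form_against_quadrature(self):
        # peak of the convolution integral, computed numerically
        from scipy.optimize import minimize_scalar

        tau, ts = 20.0, 3.0
        f = lambda t: -(ts / (tau - ts)) * (np.exp(-t / tau) - np.exp(-t / ts))
        res = minimize_scalar(f, bounds=(0.1, 60.0), method="bounded")
        assert weight_to_psp(1.0, "EE") == pytest.approx(60.0 * (-res.fun), rel=1e-6)

    def test_inhibitory_sign(self):
        assert weight_to_psp(0.4, "IE") < 0

    def test_degenerate_tau_limit(self):
        from lifsorn.params import NeuronParams

        p = NeuronParams(tau_e=20.0)  # tau_syn == tau_m
        v = weight_to_psp(1.0, "EE", p)
        assert v == pytest.approx(60.0 * np.exp(-1.0), rel=1e-9)
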