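import numpy as np
import pytest

from conftest import state_labels
from popmanifold import dynamics
from popmanifold.behavior import (
    LICK_RATE_CONSTANT,
    LickOnsetParams,
    build_pseudo_trials,
    detect_cluster_onset,
    detect_lick_onset,
    first2s_lick_rate,
    lick_similarity,
    rate_matched_selection,
    session_lick_onsets,
    smooth_licks,
)


class TestLickOnset:
    def test_rate_constants(self):
        assert LICK_RATE_CONSTANT == {"water": 0.1, "food": 0.35}

    def test_zero_licks_gives_none(self):
        params = LickOnsetParams(mu=2.0, sigma=1.0, C=0.1, threshold_s=1 / 2.1)
        assert detect_lick_onset(np.array([]), cue_time=0.0, params=params) is None

    def test_burst_after_sparse_licks_detected(self):
        # 1 Hz sparse licks then an 8 Hz burst: the threshold separates them
        params = LickOnsetParams(mu=3.0, sigma=2.0, C=0.1, threshold_s=1 / 3.2)
        sparse = np.array([0.3, 1.4, 2.9])       # intervals > 1 s > threshold
        t_star = 3.4
        burst = t_star + np.arange(6) * 0.125    # 8 Hz
        onset = detect_lick_onset(
            np.concatenate([sparse, burst]), cue_time=0.0, params=params
        )
        assert onset == pytest.approx(t_star)

    def test_threshold_formula(self):
        trial_licks = [np.array([0.1, 0.2, 0.3]), np.array([0.15])]
        cues = np.array([0.0, 0.0])
        params = LickOnsetParams.from_trials(trial_licks, cues, C=0.1)
        rates = np.array([6.0, 2.0])  # licks in first 0.5 s / 0.5 s
        assert params.mu == pytest.approx(rates.mean())
        assert params.sigma == pytest.approx(rates.std())
        assert params.threshold_s == pytest.approx(
            1.0 / (rates.mean() + 0.1 * rates.std())
        )

    def test_translation_equivariance(self):
        params = LickOnsetParams(mu=3.0, sigma=2.0, C=0.1, threshold_s=1 / 3.2)
        licks = np.array([0.5, 1.8, 2.0, 2.1, 2.25])
        base = detect_lick_onset(licks, 0.0, params)
        shifted = detect_lick_onset(licks + 100.0, 100.0, params)
        assert shifted == pytest.approx(base + 100.0)

    def test_session_onsets_recover_ground_truth(self, small_session):
        from popmanifold.preprocess import preprocess_session

        session, truth, _ = small_session
        binned = preprocess_session(session)
        onsets, params = session_lick_onsets(
            binned.bin_events, binned.trial_table(), "water"
        )
        responding = ~np.isnan(truth.lick_onsets)
        detected = ~np.isnan(onsets)
        assert detected[responding].mean() > 0.9
        both = responding & detected
        err = np.abs(onsets[both] - truth.lick_onsets[both])
        assert np.median(err) < 0.1


class TestClusterOnset:
    def test_onset_lag_recovery(self, small_binned):
        binned, truth = small_binned
        labels = state_labels(truth, binned.n_bins)
        trials = truth.trials
        tm = dynamics.build_trial_matrix(labels, trials)
        onsets_lick, _ = session_lick_onsets(
            binned.bin_events, binned.trial_table(), "water"
        )
        rew = np.flatnonzero(tm.classes == "reward_hit")
        rtm = dynamics.TrialMatrix(
            tm.sequences[rew], tm.classes[rew], tm.onsets[rew]
        )
        cue_times = trials["cue_time_s"].to_numpy()[rew]
        ons, chosen = detect_cluster_onset(
            rtm, onsets_lick[rew], cue_times, binned.bin_s
        )
        lag = ons - onsets_lick[rew]
        assert chosen in (3, 5, 2)  # a reward-sequence state
        assert 0.75 <= np.nanmedian(lag) <= 1.25

    def test_onsets_track_lick_onset_order(self, small_binned):
        from scipy.stats import spearmanr

        binned, truth = small_binned
        labels = state_labels(truth, binned.n_bins)
        tm = dynamics.build_trial_matrix(labels, truth.trials)
        rew = np.flatnonzero(tm.classes == "reward_hit")
        rtm = dynamics.TrialMatrix(tm.sequences[rew], tm.classes[rew], tm.onsets[rew])
        cue_times = truth.trials["cue_time_s"].to_numpy()[rew]
        lick = truth.lick_onsets[rew]
        ons, _ = detect_cluster_onset(rtm, lick, cue_times, binned.bin_s)
        ok = ~np.isnan(ons)
        # ground-truth latent onsets are lick onset + ~1 s, so detected
        # onsets relative to cue should track lick onsets strongly
        rho = spearmanr(ons[ok] - cue_times[ok], lick[ok] - cue_times[ok]).statistic
        assert rho > 0.5


class TestLickSimilarity:
    def test_identical_patterns_hit_epsilon_cap(self):
        a = np.zeros(310); a[::31] = 1
        assert lick_similarity(a, a) == pytest.approx(1e6)

    def test_matches_brute_force_smoothing(self):
        # all-zero vs all-one with end truncation and fixed 1/100 divisor
        a = np.zeros(310)
        b = np.ones(310)
        sb = np.array([b[i: i + 100].sum() / 100 for i in range(310)])
        expected = 1.0 / (1e-6 + np.linalg.norm(sb))
        assert lick_similarity(a, b) == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(smooth_licks(b), sb, atol=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = (rng.random(310) < 0.1).astype(float)
        b = (rng.random(310) < 0.2).astype(float)
        assert lick_similarity(a, b) == pytest.approx(lick_similarity(b, a))


class TestPseudoTrials:
    def test_hand_built_bouts(self):
        # bouts at 10, 20, 30 s: the bout-starting pair is (t, t+0.1)
        licks = []
        for t0 in (10.0, 20.0, 30.0):
            licks.extend(t0 + np.arange(8) * 0.125)
        pt = build_pseudo_trials(
            np.array(licks), epoch=(0.0, 40.0), gap_s=1.0, min_count=2
        )
        # onset = second lick of the pair whose preceding gap exceeds 1 s;
        # the first bout has no preceding lick, so candidates are bouts 2, 3
        np.testing.assert_allclose(pt.onsets_s, [20.0, 30.0])
        assert pt.gap_used_s == 1.0

    def test_windows_pairwise_disjoint(self):
        rng = np.random.default_rng(1)
        licks = np.sort(rng.uniform(0, 100, 400))
        pt = build_pseudo_trials(licks, epoch=(0.0, 100.0), gap_s=1.0, min_count=1)
        w = pt.windows_s
        assert np.all(w[1:, 0] >= w[:-1, 1])

    def test_fallback_gap_triggered(self):
        licks = np.arange(0.0, 30.0, 0.2)  # continuous 5 Hz licking
        pt = build_pseudo_trials(
            licks, epoch=(0.0, 30.0), gap_s=1.0, fallback_gap_s=0.15, min_count=1
        )
        assert pt.gap_used_s == 0.15

    def test_no_candidates_raises(self):
        licks = np.arange(0.0, 10.0, 0.05)
        with pytest.raises(ValueError, match="no pseudo-trial"):
            build_pseudo_trials(
                licks, epoch=(0.0, 10.0), gap_s=1.0, fallback_gap_s=0.06,
                min_count=1,
            )

    def test_free_epoch_from_generator(self, small_session):
        session, truth, cfg = small_session
        ev = session.events
        start = float(ev.loc[ev["event"] == "epoch_start", "time_s"].iloc[0])
        end = float(ev.loc[ev["event"] == "epoch_end", "time_s"].iloc[0])
        licks = ev.loc[ev["event"] == "lick", "time_s"].to_numpy()
        labels = state_labels(truth)
        pt = build_pseudo_trials(
            licks, epoch=(start, end), labels=labels,
            bin_s=15 / cfg.frame_hz, frame_hz=cfg.frame_hz,
        )
        assert pt.onsets_s.size >= 5
        assert pt.label_sequences is not None
        assert pt.lick_patterns.shape[1] == int(round(6 * cfg.frame_hz))

    def test_free_dynamics_less_similar_to_task_reward(self, small_session):
        session, truth, cfg = small_session
        labels = state_labels(truth)
        tm = dynamics.build_trial_matrix(labels, truth.trials)
        rew = tm.sequences[tm.classes == "reward_hit"]

        ev = session.events
        start = float(ev.loc[ev["event"] == "epoch_start", "time_s"].iloc[0])
        end = float(ev.loc[ev["event"] == "epoch_end", "time_s"].iloc[0])
        licks = ev.loc[ev["event"] == "lick", "time_s"].to_numpy()
        pt = build_pseudo_trials(
            licks, epoch=(start, end), labels=labels,
            bin_s=15 / cfg.frame_hz,
        )
        pseudo = pt.label_sequences.astype(float)
        n = min(pseudo.shape[1], rew.shape[1])

        def mean_sim(A, B):
            An = A[:, :n] / np.linalg.norm(A[:, :n], axis=1, keepdims=True)
            Bn = B[:, :n] / np.linalg.norm(B[:, :n], axis=1, keepdims=True)
            return (An @ Bn.T).mean()

        within_task = mean_sim(rew.astype(float), rew.astype(float))
        task_vs_free = mean_sim(rew.astype(float), pseudo)
        assert task_vs_free < within_task


class TestRateMatching:
    def test_band_filter_against_direct_count(self):
        rng = np.random.default_rng(2)
        task = rng.normal(6.0, 1.0, 40)
        pseudo = np.concatenate([rng.normal(6.0, 1.0, 30), rng.normal(12.0, 0.5, 30)])
        keep = rate_matched_selection(task, pseudo)
        mu, sd = task.mean(), task.std()
        expected = np.flatnonzero((pseudo >= mu - sd) & (pseudo <= mu + sd))
        np.testing.assert_array_equal(keep, expected)

    def test_extreme_rate_dropped(self):
        task = np.full(10, 5.0)
        task[0] = 6.0  # nonzero SD
        mu, sd = task.mean(), task.std()
        keep = rate_matched_selection(task, np.array([mu, mu + 2 * sd]))
        assert keep.tolist() == [0]

    def test_first2s_rate(self):
        licks = np.array([0.1, 0.5, 1.9, 2.5, 10.0])
        rates = first2s_lick_rate(licks, np.array([0.0, 10.0]))
        np.testing.assert_allclose(rates, [1.5, 0.5])
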