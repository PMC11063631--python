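import numpy as np
import pytest

from conftest import state_labels
from popmanifold import synthio
from popmanifold.dynamics import (
    TrialMatrix,
    build_trial_matrix,
    decode_across,
    mean_activity_sequences,
    pairwise_trial_similarity,
    baseline_decoder,
    state_axis_projection,
    transition_matrix,
    translate_labels,
    trial_similarity,
    apply_label_mapping,
)


@pytest.fixture(scope="module")
def paired_truth():
    perm = np.array([0, 4, 6, 1, 7, 2, 5, 3])
    cfg = synthio.SimConfig(
        n_neurons=10, n_trials_per_class=40, seed=21, free_epoch=False, noise_sd=0.5
    )
    (sa, ta), (sb, tb) = synthio.generate_paired_sessions(cfg, perm)
    return ta, tb, perm


def truth_mapping(perm):
    def lab(s):
        return -1 if s == 0 else int(s)

    return {lab(perm[i]): lab(i) for i in range(8)}


class TestTrialMatrix:
    def test_rows_are_twenty_labels(self, paired_truth):
        ta, _, _ = paired_truth
        tm = build_trial_matrix(state_labels(ta), ta.trials)
        assert tm.sequences.shape == (len(ta.trials) - tm.n_dropped, 20)

    def test_rewarded_rows_contain_reward_sequence_states(self, paired_truth):
        ta, _, _ = paired_truth
        tm = build_trial_matrix(state_labels(ta), ta.trials)
        rew = tm.sequences[tm.classes == "reward_hit"]
        for state in (3, 5, 2):
            assert np.mean((rew == state).any(axis=1)) > 0.9

    def test_all_sentinel_session(self):
        import pandas as pd

        labels = np.full(200, -1)
        trials = pd.DataFrame(
            {"trial_class": ["reward_hit"] * 3, "cue_bin": [0, 50, 100],
             "cue_time_s": [0.0, 25.0, 50.0]}
        )
        tm = build_trial_matrix(labels, trials)
        assert (tm.sequences == -1).all()

    def test_edge_trials_dropped(self):
        import pandas as pd

        labels = np.full(30, 2)
        trials = pd.DataFrame(
            {"trial_class": ["reward_hit"] * 2, "cue_bin": [0, 20],
             "cue_time_s": [0.0, 10.0]}
        )
        tm = build_trial_matrix(labels, trials)
        assert tm.sequences.shape[0] == 1 and tm.n_dropped == 1


class TestTrialSimilarity:
    def test_identical_sequences(self):
        seq = np.array([-1, -1, 2, 2])
        assert trial_similarity(seq, seq) == pytest.approx(1.0)

    def test_printed_example(self):
        a = np.array([-1, -1, 2, 2])
        b = np.array([-1, -1, -1, 2])
        assert trial_similarity(a, b) == pytest.approx(4 / np.sqrt(70), abs=1e-12)

    def test_all_sentinel_pair(self):
        a = np.full(20, -1)
        assert trial_similarity(a, a) == pytest.approx(1.0)

    def test_pairwise_matrix_symmetric_pooled_lower_triangle(self, paired_truth):
        ta, _, _ = paired_truth
        tm = build_trial_matrix(state_labels(ta), ta.trials)
        S, pooled = pairwise_trial_similarity(tm)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        m = S.shape[0]
        assert pooled.shape == (m * (m - 1) // 2,)

    def test_rewarded_trials_more_stereotyped_than_correct_rejections(
        self, paired_truth
    ):
        ta, _, _ = paired_truth
        tm = build_trial_matrix(state_labels(ta), ta.trials)
        S, _ = pairwise_trial_similarity(tm)

        def within(cls):
            idx = np.flatnonzero(tm.classes == cls)
            sub = S[np.ix_(idx, idx)]
            return sub[np.tril_indices_from(sub, k=-1)].mean()

        assert within("reward_hit") > within("aversive_cr")


class TestTransitionMatrix:
    def test_rows_stochastic(self, paired_truth):
        ta, _, _ = paired_truth
        tm = transition_matrix(state_labels(ta))
        np.testing.assert_allclose(tm.P.sum(axis=1), 1.0, atol=1e-9)
        assert tm.P.shape == (8, 8)

    def test_deterministic_cycle_rows_are_unit_vectors(self):
        seq = np.array([-1, 1, 2, 3] * 50)
        tm = transition_matrix(seq)
        i1 = list(tm.labels).index(1)
        i2 = list(tm.labels).index(2)
        assert tm.P[i1, i2] == 1.0

    def test_missing_label_rejected(self):
        seq = np.array([-1, 1, 2] * 30)
        full = np.array([-1, 1, 2, 3, 4, 5, 6, 7])
        with pytest.raises(ValueError, match="never occur"):
            transition_matrix(seq, require_labels=full)

    def test_run_boundary_transitions_excluded(self):
        seq = np.concatenate([np.full(50, 1), np.full(50, 2)])
        seq[0] = -1; seq[51] = -1  # ensure sentinel present
        with_bound = transition_matrix(seq, run_bin_bounds=[(0, 50), (50, 100)])
        i1 = list(with_bound.labels).index(1)
        i2 = list(with_bound.labels).index(2)
        assert with_bound.P[i1, i2] == 0.0

    def test_paired_sessions_conjugate(self, paired_truth):
        ta, tb, perm = paired_truth
        pa = transition_matrix(state_labels(ta))
        pb = transition_matrix(state_labels(tb))
        # align by label value: row of state i in A equals row of perm[i] in B
        order_a = np.argsort(pa.labels)
        A = pa.P[np.ix_(order_a, order_a)]   # labels -1,1..7 sorted
        idx_b = {lab: i for i, lab in enumerate(pb.labels)}
        lab_sorted_a = np.sort(pa.labels)

        def to_b(lab):
            s = 0 if lab == -1 else lab
            t = perm[s]
            return idx_b[-1 if t == 0 else t]

        rows_b = [to_b(l) for l in lab_sorted_a]
        B = pb.P[np.ix_(rows_b, rows_b)]
        assert np.abs(A - B).max() < 0.05


class TestTranslation:
    def test_self_translation_is_identity(self, paired_truth):
        ta, _, _ = paired_truth
        tm = transition_matrix(state_labels(ta))
        mapping = translate_labels(tm, tm)
        assert mapping == {int(l): int(l) for l in tm.labels}

    def test_recovers_true_permutation(self, paired_truth):
        ta, tb, perm = paired_truth
        mapping = translate_labels(
            transition_matrix(state_labels(ta)),
            transition_matrix(state_labels(tb)),
        )
        assert mapping == truth_mapping(perm)

    def test_mapping_is_bijection(self, paired_truth):
        ta, tb, _ = paired_truth
        mapping = translate_labels(
            transition_matrix(state_labels(ta)),
            transition_matrix(state_labels(tb)),
        )
        assert sorted(mapping.keys()) == sorted(mapping.values())


class TestDecoding:
    def test_cross_session_rewarded_decoding(self, paired_truth):
        ta, tb, perm = paired_truth
        ref = build_trial_matrix(state_labels(ta), ta.trials)
        train = build_trial_matrix(state_labels(tb), tb.trials)
        mapping = translate_labels(
            transition_matrix(state_labels(ta)),
            transition_matrix(state_labels(tb)),
        )
        res = decode_across(ref, train, mapping, n_perm=200, seed=0)
        assert res.accuracy["reward_hit"] > 0.8
        assert res.p["reward_hit"] < 0.01
        # classes without stereotyped dynamics stay inside the null band
        for cls in ("aversive_cr", "neutral_fa"):
            lo, hi = np.quantile(res.null_by_class[cls], [0.025, 0.975])
            assert lo <= res.accuracy[cls] <= hi

    def test_translation_invariant_to_relabeling(self, paired_truth):
        # permuting the training session's labels and recomputing the mapping
        # must leave the predictions unchanged
        ta, tb, perm = paired_truth
        ref = build_trial_matrix(state_labels(ta), ta.trials)
        train = build_trial_matrix(state_labels(tb), tb.trials)
        pa = transition_matrix(state_labels(ta))
        pb = transition_matrix(state_labels(tb))
        res1 = decode_across(ref, train, translate_labels(pa, pb), seed=1, n_perm=10)

        extra = np.array([0, 3, 1, 2, 5, 4, 7, 6])
        relabeled = apply_label_mapping(train, truth_mapping(extra))
        pb2 = transition_matrix(
            apply_labels_to_sequence(state_labels(tb), truth_mapping(extra))
        )
        res2 = decode_across(
            ref, relabeled, translate_labels(pa, pb2), seed=1, n_perm=10
        )
        np.testing.assert_array_equal(res1.predicted, res2.predicted)

    def test_self_decoding_rewarded_consistency(self, paired_truth):
        ta, _, _ = paired_truth
        tm = build_trial_matrix(state_labels(ta), ta.trials)
        res = decode_across(tm, tm, None, n_perm=50, seed=2)
        assert res.accuracy["reward_hit"] >= res.null_by_class["reward_hit"].max()


def apply_labels_to_sequence(labels, mapping):
    out = labels.copy()
    for src, dst in mapping.items():
        out[labels == src] = dst
    return out


class TestBaselines:
    def test_state_axis_anchor_scaling(self, small_binned):
        binned, _ = small_binned
        T = binned.n_bins
        thirsty = np.zeros(T, bool); thirsty[: T // 10] = True
        quenched = np.zeros(T, bool); quenched[-T // 10:] = True
        proj = state_axis_projection(binned.z, thirsty, quenched)
        x_t = binned.z[:, thirsty].mean(axis=1)
        x_q = binned.z[:, quenched].mean(axis=1)
        axis = x_t - x_q
        assert ((x_t - x_q) @ axis) / (axis @ axis) == pytest.approx(1.0)
        assert ((x_q - x_q) @ axis) / (axis @ axis) == pytest.approx(0.0)
        assert proj.shape == (T,)

    def test_cluster_decoder_beats_baselines_on_identity_stereotypy(
        self, small_binned
    ):
        binned, truth = small_binned
        labels = state_labels(truth, binned.n_bins)
        trials = truth.trials
        tm = build_trial_matrix(labels, trials)
        res_cluster = decode_across(tm, tm, None, n_perm=10, seed=3)

        feats = mean_activity_sequences(binned.z, tm)
        res_mean = baseline_decoder(
            feats, tm.classes, feats, tm.classes, n_perm=10, seed=3
        )
        assert (
            res_cluster.accuracy["reward_hit"] >= res_mean.accuracy["reward_hit"]
        )

    def test_zero_matrix_rejected(self):
        feats = np.zeros((4, 20))
        with pytest.raises(ValueError, match="zero-norm"):
            baseline_decoder(feats, np.array(["a"] * 4), feats, np.array(["a"] * 4))
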