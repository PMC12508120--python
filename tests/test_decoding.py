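"""Balanced leave-one-out decoding: balancing, recovery, nulls, ablation."""

import numpy as np
import pytest
from scipy import stats

import revdecode as rd
from revdecode.alignment import EpochDefinition, EpochTensor
from revdecode.decoding import CONDITIONS
from revdecode.errors import ConfigurationError, SessionNotDecodableError

from conftest import simulate_recorded_session


def _labels(sides, outcomes):
    return rd.TrialLabels(side=np.array(sides), outcome=np.array(outcomes))


def _balanced_labels(n_per=10):
    sides, outcomes = [], []
    for c in CONDITIONS * n_per:
        sides.append(c[0])
        outcomes.append("win" if c[1] == "W" else "lose")
    return _labels(sides, outcomes)


def _tensor_from_bin_activity(activity, window=(-1.0, 3.0), anchor_frame=21):
    """EpochTensor with a single bin holding the given cells x trials data."""
    activity = np.asarray(activity, float)
    return EpochTensor(
        values=activity[:, None, :],
        bin_centers=np.array([-0.2]),
        epoch=EpochDefinition("choice", "t_choice", window),
        anchor_frame=anchor_frame,
        fps=20.0,
        trial_index_map=np.arange(1, activity.shape[1] + 1),
    )


class TestBalancedTrainIndices:
    def test_equal_counts_give_min_rule(self):
        labels = _balanced_labels(10)  # 10 per condition, interleaved
        test_trial = 0  # an LW trial
        out = rd.balanced_train_indices(labels, test_trial, seed=1)
        assert len(out) == 36
        assert test_trial not in out
        cond = labels.condition[out]
        counts = {c: (cond == c).sum() for c in CONDITIONS}
        assert counts == {c: 9 for c in CONDITIONS}

    def test_test_trial_always_excluded(self):
        labels = _balanced_labels(5)
        for t in range(len(labels)):
            assert t not in rd.balanced_train_indices(labels, t, seed=7)

    def test_empty_condition_raises(self):
        labels = _labels(
            ["L"] * 5 + ["R"] * 13,
            ["win"] * 5 + ["win"] * 7 + ["lose"] * 6,
        )  # no left-unrewarded trials
        with pytest.raises(SessionNotDecodableError):
            rd.balanced_train_indices(labels, 0, seed=0)

    def test_fresh_draw_per_test_trial_and_seed(self):
        labels = _balanced_labels(10)
        a = rd.balanced_train_indices(labels, 0, seed=1)
        b = rd.balanced_train_indices(labels, 0, seed=2)
        c = rd.balanced_train_indices(labels, 0, seed=1)
        assert not np.array_equal(a, b)
        np.testing.assert_array_equal(a, c)

    def test_class_priors_exactly_balanced(self):
        labels = _balanced_labels(8)
        out = rd.balanced_train_indices(labels, 3, seed=5)
        assert (labels.side[out] == "L").sum() == len(out) // 2
        assert (labels.outcome[out] == "win").sum() == len(out) // 2


class TestLooDecode:
    def test_single_perfect_cell_decodes_exactly(self):
        labels = _balanced_labels(8)
        act = np.zeros((3, len(labels)))
        act[1] = np.where(labels.side == "L", 1.0, -1.0)
        res = rd.loo_decode(_tensor_from_bin_activity(act), labels, "side", seed=0)
        assert res.accuracy[0] == 1.0

    def test_correctness_rows_reproduce_accuracy(self, planted_recorded_session):
        s = planted_recorded_session
        pre = rd.pre_event_bin(s["tensor"])
        res = rd.loo_decode(
            s["tensor"], s["labels"], "side", seed=3, bins=np.array([pre, pre + 4])
        )
        np.testing.assert_allclose(res.correctness.mean(axis=0), res.accuracy)

    def test_null_activity_decodes_at_chance(self, null_recorded_session):
        s = null_recorded_session
        pre = rd.pre_event_bin(s["tensor"])
        res = rd.loo_decode(s["tensor"], s["labels"], "side", seed=4,
                            bins=np.array([pre]))
        n = s["tensor"].n_trials
        assert abs(res.accuracy[0] - 0.5) <= 1.96 * np.sqrt(0.25 / n)

    def test_planted_side_cells_decode_above_ninety(self, planted_recorded_session):
        s = planted_recorded_session
        pre = rd.pre_event_bin(s["tensor"])
        res = rd.loo_decode(s["tensor"], s["labels"], "side", seed=5,
                            bins=np.array([pre]))
        assert res.accuracy[0] > 0.9

    def test_accuracy_invariant_under_cell_permutation_and_shift(self):
        """Permuting cells or adding a common offset leaves accuracy
        unchanged; a common rescaling leaves it unchanged when the classes
        are well separated (with a fixed box constraint, extreme rescaling
        changes the effective regularization, so exact scale invariance
        holds only in the separable regime)."""
        labels = _balanced_labels(6)
        rng = np.random.default_rng(8)
        act = rng.normal(size=(5, len(labels))) * 0.1
        act[0] += np.where(labels.side == "L", 1.0, -1.0)
        base = rd.loo_decode(_tensor_from_bin_activity(act), labels, "side", seed=9)
        perm = rng.permutation(5)
        permed = rd.loo_decode(
            _tensor_from_bin_activity(act[perm]), labels, "side", seed=9
        )
        shifted = rd.loo_decode(
            _tensor_from_bin_activity(act + 1.0), labels, "side", seed=9
        )
        scaled = rd.loo_decode(
            _tensor_from_bin_activity(act * 3.0), labels, "side", seed=9
        )
        assert base.accuracy[0] == permed.accuracy[0]
        assert base.accuracy[0] == shifted.accuracy[0]
        assert base.accuracy[0] == scaled.accuracy[0]

    def test_deterministic_given_seed(self, planted_recorded_session):
        s = planted_recorded_session
        a = rd.loo_decode(s["tensor"], s["labels"], "outcome", seed=11,
                          bins=np.array([0]))
        b = rd.loo_decode(s["tensor"], s["labels"], "outcome", seed=11,
                          bins=np.array([0]))
        np.testing.assert_array_equal(a.correctness, b.correctness)
        np.testing.assert_allclose(a.weights, b.weights)


class TestShuffleNull:
    def test_shuffle_breaks_planted_coupling(self, planted_recorded_session):
        s = planted_recorded_session
        pre = rd.pre_event_bin(s["tensor"])
        null = rd.shuffle_null(
            s["tensor"], s["labels"], "side", n_shuffle=20, seed=13,
            bins=np.array([pre]),
        )
        n = s["tensor"].n_trials * 20
        assert abs(null[0] - 0.5) <= 1.96 * np.sqrt(0.25 / n) + 0.05

    def test_deterministic_and_param_checked(self, planted_recorded_session):
        s = planted_recorded_session
        kw = dict(target="side", n_shuffle=2, seed=14, bins=np.array([0]))
        a = rd.shuffle_null(s["tensor"], s["labels"], **kw)
        b = rd.shuffle_null(s["tensor"], s["labels"], **kw)
        np.testing.assert_allclose(a, b)
        with pytest.raises(ConfigurationError):
            rd.shuffle_null(s["tensor"], s["labels"], "side", n_shuffle=0, seed=0)


class TestAblation:
    def test_k_zero_equals_baseline(self, planted_recorded_session):
        s = planted_recorded_session
        pre = rd.pre_event_bin(s["tensor"])
        curve = rd.ablation_curve(s["tensor"], s["labels"], "side", ks=[0], seed=15)
        base = rd.loo_decode(s["tensor"], s["labels"], "side", seed=15,
                             bins=np.array([pre]))
        assert curve[0] == base.accuracy[0]

    def test_removing_all_signal_cells_restores_chance(self):
        """Exactly 4 of 16 cells carry signal; ablating 4 leaves noise."""
        s = simulate_recorded_session(
            block_length=20, n_cells=16, frac_side=0.25, seed=16
        )
        n_signal = sum(c.selectivity_class == "side" for c in s["cells"])
        assert n_signal == 4
        curve = rd.ablation_curve(s["tensor"], s["labels"], "side",
                                  ks=[0, n_signal], seed=17)
        n = s["tensor"].n_trials
        assert curve[0] > 0.9
        assert abs(curve[1] - 0.5) <= 1.96 * np.sqrt(0.25 / n)

    def test_k_too_large_rejected(self, planted_recorded_session):
        s = planted_recorded_session
        with pytest.raises(ConfigurationError):
            rd.ablation_curve(s["tensor"], s["labels"], "side",
                              ks=[s["tensor"].n_cells], seed=0)

    def test_accuracy_declines_with_k_over_sessions(self):
        """Spearman(accuracy, k) <= 0 in nearly all sessions (sign test)."""
        neg = 0
        n_sessions = 8
        for i in range(n_sessions):
            s = simulate_recorded_session(
                block_length=15, n_cells=12, frac_side=0.5,
                modulation_depth=1.0, seed=30 + i,
            )
            curve = rd.ablation_curve(s["tensor"], s["labels"], "side",
                                      ks=[0, 2, 4, 6], seed=40 + i)
            rho = stats.spearmanr(curve, [0, 2, 4, 6]).statistic
            neg += rho <= 0
        # sign test: >= 7 of 8 non-positive correlations, p < 0.05
        assert neg >= 7
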