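"""Strategy metrics: Win-Stay, Lose-Shift, perseveration, flexibility, latencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import revdecode as rd
from revdecode.behavior import ls_indicator, ws_indicator
from revdecode.errors import ConfigurationError, NotComputableError

from conftest import toy_trials

# the hand-enumerated 6-trial sequence: (choice, reward)
SIX = (["L", "L", "R", "R", "R", "L"], [1, 0, 0, 1, 1, 0])


class TestWinStayLoseShift:
    def test_six_trial_sequence_win_stay(self):
        """Events at t=2 (prev win, stay) and t=5 (prev win, stay): 2/5."""
        assert rd.win_stay(toy_trials(*SIX)) == pytest.approx(0.4)

    def test_six_trial_sequence_lose_shift(self):
        """Only t=3 (prev loss, L->R): 1/5."""
        assert rd.lose_shift(toy_trials(*SIX)) == pytest.approx(0.2)

    def test_perfect_stayer(self):
        trials = toy_trials(["L"] * 10, [1] * 10)
        assert rd.win_stay(trials) == 1.0
        assert rd.lose_shift(trials) == 0.0  # no losses

    def test_perfect_loss_switcher(self):
        trials = toy_trials(["L", "R"] * 5, [0] * 10)
        assert rd.lose_shift(trials) == 1.0
        assert rd.win_stay(trials) == 0.0  # no wins

    def test_conditional_denominator_option(self):
        trials = toy_trials(*SIX)
        # 3 post-win trials (t=2,5,6), 2 stays; 2 post-loss trials (t=3,4), 1 shift
        assert rd.win_stay(trials, denominator="conditional") == pytest.approx(2 / 3)
        assert rd.lose_shift(trials, denominator="conditional") == pytest.approx(1 / 2)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.win_stay(toy_trials(["L"], [1]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["L", "R"]), st.integers(0, 1)),
            min_size=2,
            max_size=40,
        )
    )
    def test_bounded_in_unit_interval(self, seq):
        choices = [c for c, _ in seq]
        rewards = [r for _, r in seq]
        trials = toy_trials(choices, rewards)
        for denom in ("all", "conditional"):
            assert 0.0 <= rd.win_stay(trials, denominator=denom) <= 1.0
            assert 0.0 <= rd.lose_shift(trials, denominator=denom) <= 1.0

    def test_wsls_agent_recovers_stay_probability(self):
        """A WSLS agent staying after wins with probability q shows
        conditional Win-Stay ~= q (closed-form oracle), at three q values."""
        cfg = rd.TaskConfig(schedule_id=3)
        for q in (0.55, 0.75, 0.95):
            agent = rd.AgentParams(kind="wsls", p_stay_after_win=q,
                                   p_shift_after_loss=0.6)
            ws, n = 0.0, 0
            for seed in range(8):
                trials = rd.simulate_session(cfg, agent, 500 + seed)
                ws += rd.win_stay(trials, denominator="conditional") * len(trials)
                n += len(trials)
            assert abs(ws / n - q) < 0.05


class TestPerseveration:
    def test_immediate_shifter_scores_one(self):
        trials = toy_trials(["L", "R", "L", "R"], [0, 0, 0, 1])
        assert rd.perseveration_index(trials) == 1.0

    def test_three_trial_run(self):
        trials = toy_trials(["L", "L", "L", "R"], [0, 0, 0, 1])
        assert rd.perseveration_index(trials) == 3.0

    def test_all_rewarded_not_computable(self):
        with pytest.raises(NotComputableError):
            rd.perseveration_index(toy_trials(["L", "L", "L"], [1, 1, 1]))

    def test_censoring_at_session_end(self):
        # loss run starting at trial 2 never resolves: censored at the one
        # remaining trial
        trials = toy_trials(["L", "L", "L"], [1, 0, 0])
        assert rd.perseveration_index(trials, censor=True) == 1.0
        with pytest.raises(NotComputableError):
            rd.perseveration_index(trials, censor=False)


class TestFlexibility:
    @staticmethod
    def _blocked(block_means, n_per=10):
        choices, rewards, blocks, better = [], [], [], []
        for b, m in enumerate(block_means, 1):
            good = int(round(m * n_per))
            side = "L" if b % 2 else "R"
            other = "R" if side == "L" else "L"
            for t in range(n_per):
                blocks.append(b)
                better.append(side)
                choices.append(side if t < good else other)
                rewards.append(1 if t < good else 0)
        return toy_trials(choices, rewards, blocks=blocks, better=better)

    def test_always_better_scores_one(self):
        assert rd.flexibility_index(self._blocked([1.0, 1.0, 1.0])) == 1.0

    def test_forced_block_means(self):
        """Block means (0.8, 0.6, 0.4): mean(mean(.8,.6), mean(.6,.4)) = 0.6."""
        assert rd.flexibility_index(
            self._blocked([0.8, 0.6, 0.4])
        ) == pytest.approx(0.6)

    def test_uniform_agent_near_half(self):
        cfg = rd.TaskConfig(schedule_id=3)
        agent = rd.AgentParams(kind="wsls", p_stay_after_win=0.5,
                               p_shift_after_loss=0.5)
        vals = [
            rd.flexibility_index(rd.simulate_session(cfg, agent, 600 + s))
            for s in range(40)
        ]  # 9,000 trials total
        assert abs(np.mean(vals) - 0.5) < 2 * np.sqrt(0.25 / 9000) + 0.01

    def test_requires_three_blocks(self):
        with pytest.raises(ConfigurationError):
            rd.flexibility_index(toy_trials(["L"] * 4, [1] * 4, blocks=[1] * 4))


class TestMovingStrategy:
    def test_full_window_equals_session_proportion(self):
        trials = toy_trials(*SIX)
        out = rd.moving_strategy(trials, window=len(trials))
        np.testing.assert_allclose(out["moving_ws"], ws_indicator(trials).mean())
        np.testing.assert_allclose(out["moving_ls"], ls_indicator(trials).mean())

    def test_constant_indicator_gives_constant_trace(self):
        trials = toy_trials(["L"] * 8, [1] * 8)  # WS everywhere after t=1
        out = rd.moving_strategy(trials, window=3)
        assert len(set(out["moving_ws"][2:-2])) == 1

    def test_window_five_matches_enumeration(self):
        trials = toy_trials(
            ["L", "L", "R", "R", "L", "L", "L", "R", "R", "R"],
            [1, 0, 0, 1, 1, 0, 1, 1, 0, 0],
        )
        ind = ws_indicator(trials)
        out = rd.moving_strategy(trials, window=5)["moving_ws"]
        # brute-force sliding mean over the 5 nearest trials
        expected = []
        for i in range(10):
            lo = min(max(0, i - 2), 10 - 5)
            expected.append(ind[lo : lo + 5].mean())
        np.testing.assert_allclose(out, expected)

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigurationError):
            rd.moving_strategy(toy_trials(*SIX), window=0)


class TestLatencies:
    def test_median_of_three(self):
        trials = toy_trials(["L"] * 3, [1] * 3)
        trials["init_latency"] = [1.0, 2.0, 9.0]
        assert rd.latency_summaries(trials)["median_init_latency"] == 2.0

    def test_all_unrewarded_has_no_reward_median(self):
        trials = toy_trials(["L", "R"], [0, 0])
        assert rd.latency_summaries(trials)["median_reward_latency"] is None

    def test_lognormal_median_converges_to_analytic_value(self):
        """Median of exp(N(0, 1)) is e^0 = 1."""
        from revdecode.task import LatencyModel

        agent = rd.AgentParams(
            kind="wsls",
            latency=LatencyModel(reward_mu=0.0, reward_sigma=1.0),
        )
        cfg = rd.TaskConfig(schedule_id=1)
        meds = []
        n = 0
        for seed in range(20):
            trials = rd.simulate_session(cfg, agent, 700 + seed)
            lats = trials.loc[trials["rewarded"] == 1, "reward_latency"]
            meds.append(lats.median())
            n += len(lats)
        assert abs(np.median(meds) - 1.0) < 0.05


class TestSummary:
    def test_summary_fields_consistent(self, default_session):
        _, trials = default_session
        s = rd.summarize_behavior(trials)
        assert 0.0 <= s.win_stay <= 1.0
        assert 0.0 <= s.lose_shift <= 1.0
        assert 0.0 <= s.flexibility_index <= 1.0
        assert s.p_better == pytest.approx(trials["better_chosen"].mean())
        assert len(s.moving_ws) == len(trials)

    def test_forced_better_agent_p_better_is_one(self):
        cfg = rd.TaskConfig(schedule_id=2)
        trials = rd.simulate_session(cfg, rd.AgentParams(kind="forced_better"), 1)
        s = rd.summarize_behavior(trials)
        assert s.p_better == 1.0
        assert s.flexibility_index == 1.0
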