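"""Simulation of the probabilistic reversal learning task.

A session consists of three blocks of committed trials (default 75 each,
225 total).  On every trial the animal initiates at a center stimulus and
then chooses a left or right stimulus; one side carries the higher reward
probability and the better side reverses at each block boundary.  The
probability ratio is constant over blocks 1-2 and becomes more uncertain in
block 3 (e.g. 100:0 -> 90:10 for schedule 1, down to 80:20 -> 70:30 for
schedule 3).  Rewarded trials deliver a pellet 1 s after the choice
nosepoke; unrewarded trials incur a 5 s timeout; a 10 s inter-trial
interval separates trials.

Choices are produced by parametric agents (win-stay/lose-shift, Q-learning,
or a forced better-side chooser) so that sessions spanning a wide range of
strategy-index values can be generated on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from revdecode.errors import ConfigurationError

__all__ = [
    "TaskConfig",
    "AgentParams",
    "LatencyModel",
    "simulate_session",
    "make_agent_state",
    "agent_step",
    "agent_update",
    "TRIAL_TABLE_COLUMNS",
]

#: TSV column order for a trial table; one row per committed trial.
TRIAL_TABLE_COLUMNS = [
    "index",
    "block",
    "better_side",
    "chosen_side",
    "rewarded",
    "better_chosen",
    "t_init_cue",
    "t_init",
    "t_choice",
    "t_reward_cue",
    "t_retrieval",
    "init_latency",
    "choice_latency",
    "reward_latency",
]

# (p_better, p_worse) in percent, identical for blocks 1-2, more uncertain in
# block 3.
_SCHEDULE_RATIOS = {
    1: [(100.0, 0.0), (100.0, 0.0), (90.0, 10.0)],
    2: [(90.0, 10.0), (90.0, 10.0), (80.0, 20.0)],
    3: [(80.0, 20.0), (80.0, 20.0), (70.0, 30.0)],
}


@dataclass(frozen=True)
class TaskConfig:
    """Reward schedule and event timing for one session.

    ``blocks`` holds three ``(p_better, p_worse, better_side)`` tuples with
    probabilities in percent and sides in {"L", "R"}; the better side must
    alternate between consecutive blocks (the reversal).
    """

    schedule_id: int
    blocks: tuple = ()
    block_length: int = 75
    reward_delay: float = 1.0
    iti: float = 10.0
    timeout: float = 5.0
    init_deadline: float = 40.0
    choice_deadline: float = 60.0
    first_better_side: str = "L"

    def __post_init__(self):
        if not self.blocks:
            if self.schedule_id not in _SCHEDULE_RATIOS:
                raise ConfigurationError(
                    f"unknown schedule_id {self.schedule_id}; expected 1-3"
                )
            side = self.first_better_side
            blocks = []
            for p_b, p_w in _SCHEDULE_RATIOS[self.schedule_id]:
                blocks.append((p_b, p_w, side))
                side = "R" if side == "L" else "L"
            object.__setattr__(self, "blocks", tuple(blocks))
        self._validate()

    def _validate(self):
        if len(self.blocks) != 3:
            raise ConfigurationError(
                f"expected exactly 3 blocks, got {len(self.blocks)}"
            )
        for i, (p_b, p_w, side) in enumerate(self.blocks):
            if not (0.0 <= p_w < p_b <= 100.0):
                raise ConfigurationError(
                    f"block {i + 1}: need 0 <= p_worse < p_better <= 100, "
                    f"got ({p_b}, {p_w})"
                )
            if side not in ("L", "R"):
                raise ConfigurationError(f"block {i + 1}: bad side {side!r}")
        for i in range(2):
            if self.blocks[i][2] == self.blocks[i + 1][2]:
                raise ConfigurationError(
                    f"better side must reverse between blocks {i + 1} and {i + 2}"
                )
        if self.block_length < 1:
            raise ConfigurationError("block_length must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "blocks" in d and d["blocks"]:
            d["blocks"] = tuple(tuple(b) for b in d["blocks"])
        return cls(**d)


@dataclass(frozen=True)
class LatencyModel:
    """Log-normal latency parameters: ``exp(Normal(mu, sigma))`` seconds.

    Latencies are strictly positive and right-skewed; draws above the
    relevant deadline are clipped to the deadline (the session contains only
    committed trials).
    """

    init_mu: float = np.log(2.0)
    init_sigma: float = 0.6
    choice_mu: float = np.log(1.5)
    choice_sigma: float = 0.6
    reward_mu: float = np.log(1.0)
    reward_sigma: float = 0.5


@dataclass(frozen=True)
class AgentParams:
    """Parametric choice process.

    kind
        ``"wsls"``   -- after a win, repeat the previous side with probability
        ``p_stay_after_win``; after a loss, switch with probability
        ``p_shift_after_loss``; first trial uniform.

        ``"q_learning"`` -- per-side values updated by
        ``V <- V + alpha * (r - V)`` on the chosen side; softmax choice with
        inverse temperature ``beta``.

        ``"forced_better"`` -- always chooses the currently better side
        (used for schedule calibration, not a behavioral model).
    """

    kind: str = "wsls"
    p_stay_after_win: float = 0.8
    p_shift_after_loss: float = 0.7
    alpha: float = 0.3
    beta: float = 5.0
    initial_value: float = 0.5
    latency: LatencyModel = field(default_factory=LatencyModel)

    def __post_init__(self):
        if self.kind not in ("wsls", "q_learning", "forced_better"):
            raise ConfigurationError(f"unknown agent kind {self.kind!r}")
        for name in ("p_stay_after_win", "p_shift_after_loss", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        d = dict(d)
        if "latency" in d and isinstance(d["latency"], dict):
            d["latency"] = LatencyModel(**d["latency"])
        return cls(**d)


def make_agent_state(agent: AgentParams) -> dict:
    """Mutable per-session agent state (Q-values etc.)."""
    return {
        "params": agent,
        "V": {"L": agent.initial_value, "R": agent.initial_value},
    }


def agent_step(
    state: dict,
    last_choice: str | None,
    last_reward: int | None,
    rng: np.random.Generator,
    better_side: str | None = None,
) -> str:
    """Draw the next choice ("L" or "R") from the agent's policy."""
    p = state["params"]
    if p.kind == "forced_better":
        if better_side is None:
            raise ConfigurationError("forced_better agent needs better_side")
        return better_side
    if p.kind == "wsls":
        if last_choice is None:
            return "L" if rng.random() < 0.5 else "R"
        other = "R" if last_choice == "L" else "L"
        if last_reward:
            return last_choice if rng.random() < p.p_stay_after_win else other
        return other if rng.random() < p.p_shift_after_loss else last_choice
    # q_learning: softmax on the value difference
    dv = state["V"]["L"] - state["V"]["R"]
    p_left = 1.0 / (1.0 + np.exp(-p.beta * dv))
    return "L" if rng.random() < p_left else "R"


def agent_update(state: dict, choice: str, reward: int) -> None:
    """Delta-rule value update; no-op for non-learning agents."""
    p = state["params"]
    if p.kind == "q_learning":
        v = state["V"][choice]
        state["V"][choice] = v + p.alpha * (reward - v)


def _draw_latency(rng, mu, sigma, deadline):
    return min(float(rng.lognormal(mu, sigma)), deadline)


def simulate_session(
    config: TaskConfig, agent: AgentParams, seed: int
) -> pd.DataFrame:
    """Simulate one session; returns the trial table (one row per trial).

    Columns are :data:`TRIAL_TABLE_COLUMNS`.  Timestamps are seconds from
    session start; ``t_reward_cue``, ``t_retrieval`` and ``reward_latency``
    are NaN on unrewarded trials.  Identical ``(config, agent, seed)`` give
    identical tables.
    """
    ss = np.random.SeedSequence(seed)
    rng_agent, rng_reward, rng_latency = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    state = make_agent_state(agent)
    lat = agent.latency

    rows = []
    t = 0.0
    last_choice: str | None = None
    last_reward: int | None = None
    idx = 0
    for block_i, (p_better, p_worse, better_side) in enumerate(config.blocks, 1):
        for _ in range(config.block_length):
            idx += 1
            t_init_cue = t
            init_latency = _draw_latency(
                rng_latency, lat.init_mu, lat.init_sigma, config.init_deadline
            )
            t_init = t_init_cue + init_latency
            choice = agent_step(
                state, last_choice, last_reward, rng_agent, better_side
            )
            choice_latency = _draw_latency(
                rng_latency, lat.choice_mu, lat.choice_sigma, config.choice_deadline
            )
            t_choice = t_init + choice_latency
            p_reward = (p_better if choice == better_side else p_worse) / 100.0
            rewarded = int(rng_reward.random() < p_reward)
            if rewarded:
                t_reward_cue = t_choice + config.reward_delay
                reward_latency = float(
                    rng_latency.lognormal(lat.reward_mu, lat.reward_sigma)
                )
                t_retrieval = t_reward_cue + reward_latency
                trial_end = t_retrieval
            else:
                t_reward_cue = np.nan
                reward_latency = np.nan
                t_retrieval = np.nan
                trial_end = t_choice + config.timeout
            rows.append(
                {
                    "index": idx,
                    "block": block_i,
                    "better_side": better_side,
                    "chosen_side": choice,
                    "rewarded": rewarded,
                    "better_chosen": int(choice == better_side),
                    "t_init_cue": t_init_cue,
                    "t_init": t_init,
                    "t_choice": t_choice,
                    "t_reward_cue": t_reward_cue,
                    "t_retrieval": t_retrieval,
                    "init_latency": init_latency,
                    "choice_latency": choice_latency,
                    "reward_latency": reward_latency,
                }
            )
            agent_update(state, choice, rewarded)
            last_choice, last_reward = choice, rewarded
            t = trial_end + config.iti
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)


def session_duration(trials: pd.DataFrame, config: TaskConfig) -> float:
    """Seconds from session start until after the last trial's ITI."""
    last = trials.iloc[-1]
    end = last["t_retrieval"] if last["rewarded"] else last["t_choice"] + config.timeout
    return float(end) + config.iti
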