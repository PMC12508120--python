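"""Shared fixtures: small simulated sessions and hand-built trial tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import revdecode as rd
from revdecode.alignment import CHOICE_EPOCH
from revdecode.task import TRIAL_TABLE_COLUMNS, session_duration


def toy_trials(choices, rewards, blocks=None, better=None, trial_gap=20.0):
    """Build a consistent trial table from choice/reward sequences.

    Timestamps are laid out on a regular grid (one trial every
    ``trial_gap`` seconds) so alignment code can run on the result.
    """
    n = len(choices)
    blocks = blocks if blocks is not None else [1] * n
    better = better if better is not None else ["L"] * n
    rows = []
    for t in range(n):
        t0 = t * trial_gap
        rewarded = int(rewards[t])
        t_choice = t0 + 3.0
        rows.append(
            {
                "index": t + 1,
                "block": blocks[t],
                "better_side": better[t],
                "chosen_side": choices[t],
                "rewarded": rewarded,
                "better_chosen": int(choices[t] == better[t]),
                "t_init_cue": t0,
                "t_init": t0 + 1.5,
                "t_choice": t_choice,
                "t_reward_cue": t_choice + 1.0 if rewarded else np.nan,
                "t_retrieval": t_choice + 2.0 if rewarded else np.nan,
                "init_latency": 1.5,
                "choice_latency": 1.5,
                "reward_latency": 1.0 if rewarded else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)


def simulate_recorded_session(
    schedule_id=3,
    block_length=40,
    agent=None,
    n_cells=40,
    frac_side=0.0,
    frac_outcome=0.0,
    frac_retrieval=0.0,
    modulation_depth=3.0,
    seed=0,
):
    """Task + traces + choice-epoch tensor + labels for one synthetic session."""
    cfg = rd.TaskConfig(schedule_id=schedule_id, block_length=block_length)
    agent = agent or rd.AgentParams(kind="wsls")
    ss = np.random.SeedSequence(seed)
    s_task, s_cells, s_traces = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    trials = rd.simulate_session(cfg, agent, s_task)
    cells = rd.CellPopulation.mixed(
        n_cells,
        frac_side=frac_side,
        frac_outcome=frac_outcome,
        frac_retrieval=frac_retrieval,
        modulation_depth=modulation_depth,
        seed=s_cells,
    )
    duration = session_duration(trials, cfg)
    traces = rd.generate_traces(
        trials, cells, duration, s_traces, reward_delay=cfg.reward_delay
    )
    tensor = rd.bin_downsample(rd.extract_epoch(traces, trials, CHOICE_EPOCH))
    labels = rd.make_labels(trials)
    return {
        "config": cfg,
        "trials": trials,
        "cells": cells,
        "traces": traces,
        "tensor": tensor,
        "labels": labels,
    }


def ws_linked_cohort(rep_seed, n_sessions=20, block_length=30):
    """Simulate a cohort in which Win-Stay drives planted decodability.

    Each session draws an independent WSLS agent (p_stay in [0.5, 1.0],
    p_shift in [0.4, 0.9]); the planted side-cell modulation depth is a
    fixed increasing function of the session's measured Win-Stay, so
    decoding accuracy at the pre-choice bin is causally driven by WS.
    Returns the fitted accuracy GLM and the per-session summaries.
    """
    from revdecode.alignment import CHOICE_EPOCH
    from revdecode.designs import SessionMeta
    from revdecode.task import session_duration

    rng = np.random.default_rng(np.random.SeedSequence(rep_seed))
    results, summaries, metas, ncells = [], [], [], []
    for i in range(n_sessions):
        agent = rd.AgentParams(
            kind="wsls",
            p_stay_after_win=float(rng.uniform(0.5, 1.0)),
            p_shift_after_loss=float(rng.uniform(0.4, 0.9)),
        )
        cfg = rd.TaskConfig(schedule_id=3, block_length=block_length)
        trials = rd.simulate_session(cfg, agent, int(rng.integers(2**31)))
        beh = rd.summarize_behavior(trials)
        depth = float(np.clip(0.02 + 0.5 * (beh.win_stay - 0.3), 0.0, 0.3))
        cells = rd.CellPopulation.mixed(
            20, frac_side=0.3, modulation_depth=depth,
            seed=int(rng.integers(2**31)),
        )
        traces = rd.generate_traces(
            trials, cells, session_duration(trials, cfg), int(rng.integers(2**31))
        )
        tensor = rd.bin_downsample(rd.extract_epoch(traces, trials, CHOICE_EPOCH))
        labels = rd.make_labels(trials)
        pre = rd.pre_event_bin(tensor)
        res = rd.loo_decode(
            tensor, labels, "side", seed=int(rng.integers(2**31)),
            bins=np.array([pre]),
        )
        results.append(res)
        summaries.append(beh)
        metas.append(
            SessionMeta(subject=f"s{i % 4}", area="OFC", schedule=3, session=1)
        )
        ncells.append(tensor.n_cells)
    design = rd.build_accuracy_design(results, summaries, metas, ncells,
                                      target="side")
    return rd.fit_glm(design), summaries


@pytest.fixture(scope="session")
def default_session():
    """One full-length default session (schedule 1, q-learning agent)."""
    cfg = rd.TaskConfig(schedule_id=1)
    agent = rd.AgentParams(kind="q_learning")
    return cfg, rd.simulate_session(cfg, agent, 7)


@pytest.fixture(scope="session")
def null_recorded_session():
    """Small session with 12 non-selective cells (shared, read-only)."""
    return simulate_recorded_session(
        block_length=20, n_cells=12, frac_side=0.0, seed=5
    )


@pytest.fixture(scope="session")
def planted_recorded_session():
    """Small session with 30% side cells at modulation depth 3."""
    return simulate_recorded_session(
        block_length=20, n_cells=12, frac_side=0.3, seed=6
    )
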