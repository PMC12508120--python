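"""Behavioral strategy metrics for one reversal-learning session.

Win-Stay: proportion of all trials (with a predecessor) on which the
previous trial was rewarded and the same side was chosen again.
Lose-Shift: proportion on which the previous trial was unrewarded and the
other side was chosen.  The Perseveration Index is the mean number of
trials needed to change choice after the first unrewarded trial of a loss
run.  The Flexibility Index averages the pairwise block means of the
better-choice indicator:

    FlexIndex = mean( mean(m1, m2), mean(m2, m3) )

where ``m_b`` is the mean of C_Better over block ``b`` — 1 when the chosen
side was the better side.  Latency summaries are per-session medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from revdecode.errors import ConfigurationError, NotComputableError

__all__ = [
    "BehaviorSummary",
    "win_stay",
    "lose_shift",
    "perseveration_index",
    "flexibility_index",
    "moving_strategy",
    "latency_summaries",
    "summarize_behavior",
    "ws_indicator",
    "ls_indicator",
]


@dataclass
class BehaviorSummary:
    """Session-level strategy and latency measures."""

    p_better: float
    p_better_trialwise: np.ndarray
    win_stay: float
    lose_shift: float
    perseveration_index: float | None
    flexibility_index: float
    median_init_latency: float
    median_choice_latency: float
    median_reward_latency: float | None
    moving_ws: np.ndarray
    moving_ls: np.ndarray


def _check_min_trials(trials: pd.DataFrame, n: int = 2) -> None:
    if len(trials) < n:
        raise ConfigurationError(f"need at least {n} trials, got {len(trials)}")


def ws_indicator(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial Win-Stay boolean: previous trial rewarded and side repeated.

    The first trial has no predecessor and is 0.
    """
    chosen = trials["chosen_side"].to_numpy()
    rewarded = trials["rewarded"].to_numpy()
    ind = np.zeros(len(trials), dtype=int)
    ind[1:] = (rewarded[:-1] == 1) & (chosen[1:] == chosen[:-1])
    return ind


def ls_indicator(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial Lose-Shift boolean: previous trial unrewarded, side changed."""
    chosen = trials["chosen_side"].to_numpy()
    rewarded = trials["rewarded"].to_numpy()
    ind = np.zeros(len(trials), dtype=int)
    ind[1:] = (rewarded[:-1] == 0) & (chosen[1:] != chosen[:-1])
    return ind


def win_stay(trials: pd.DataFrame, denominator: str = "all") -> float:
    """Win-Stay proportion.

    ``denominator="all"`` divides by all trials with a predecessor (N - 1);
    ``"conditional"`` divides by the number of post-win trials.
    """
    _check_min_trials(trials)
    ind = ws_indicator(trials)
    if denominator == "all":
        return float(ind[1:].sum() / (len(trials) - 1))
    if denominator == "conditional":
        n_post_win = int((trials["rewarded"].to_numpy()[:-1] == 1).sum())
        return float(ind[1:].sum() / n_post_win) if n_post_win else 0.0
    raise ConfigurationError(f"unknown denominator {denominator!r}")


def lose_shift(trials: pd.DataFrame, denominator: str = "all") -> float:
    """Lose-Shift proportion; mirrors :func:`win_stay` for losses."""
    _check_min_trials(trials)
    ind = ls_indicator(trials)
    if denominator == "all":
        return float(ind[1:].sum() / (len(trials) - 1))
    if denominator == "conditional":
        n_post_loss = int((trials["rewarded"].to_numpy()[:-1] == 0).sum())
        return float(ind[1:].sum() / n_post_loss) if n_post_loss else 0.0
    raise ConfigurationError(f"unknown denominator {denominator!r}")


def perseveration_index(trials: pd.DataFrame, censor: bool = True) -> float:
    """Mean number of trials to change choice after the first loss of a run.

    A qualifying event is an unrewarded trial that begins a loss run on a
    side (the previous trial was rewarded, was on the other side, or does
    not exist) and is followed by at least one more trial.  Runs unresolved
    at session end are censored at the remaining trial count when
    ``censor=True``, else dropped.
    """
    chosen = trials["chosen_side"].to_numpy()
    rewarded = trials["rewarded"].to_numpy()
    n = len(trials)
    counts = []
    for t in range(n - 1):  # last trial cannot qualify (nothing follows)
        if rewarded[t] != 0:
            continue
        starts_run = t == 0 or rewarded[t - 1] == 1 or chosen[t - 1] != chosen[t]
        if not starts_run:
            continue
        later = np.flatnonzero(chosen[t + 1 :] != chosen[t])
        if len(later):
            counts.append(int(later[0]) + 1)
        elif censor:
            counts.append(n - 1 - t)
    if not counts:
        raise NotComputableError("no qualifying loss events in session")
    return float(np.mean(counts))


def flexibility_index(trials: pd.DataFrame) -> float:
    """Average of pairwise block means of the better-choice indicator."""
    blocks = sorted(trials["block"].unique())
    if blocks != [1, 2, 3]:
        raise ConfigurationError(f"need exactly blocks 1-3, got {blocks}")
    m = [
        trials.loc[trials["block"] == b, "better_chosen"].mean() for b in (1, 2, 3)
    ]
    return float(np.mean([np.mean([m[0], m[1]]), np.mean([m[1], m[2]])]))


def moving_strategy(trials: pd.DataFrame, window: int = 10) -> dict:
    """Centered moving proportions of the Win-Stay and Lose-Shift indicators.

    Each position averages the ``window`` nearest trials; near the session
    edges the window slides inward so it always covers ``window`` trials
    (or the whole session when ``window >= N``).
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    n = len(trials)
    w = min(window, n)
    half = (w - 1) // 2

    def movmean(x):
        out = np.empty(n, dtype=float)
        for i in range(n):
            lo = min(max(0, i - half), n - w)
            out[i] = x[lo : lo + w].mean()
        return out

    return {
        "moving_ws": movmean(ws_indicator(trials)),
        "moving_ls": movmean(ls_indicator(trials)),
    }


def latency_summaries(trials: pd.DataFrame) -> dict:
    """Per-session median initiation, choice and reward latencies.

    The reward median covers rewarded trials only and is None when the
    session has no rewarded trial.
    """
    rewarded = trials["rewarded"] == 1
    reward_median = (
        float(trials.loc[rewarded, "reward_latency"].median())
        if rewarded.any()
        else None
    )
    return {
        "median_init_latency": float(trials["init_latency"].median()),
        "median_choice_latency": float(trials["choice_latency"].median()),
        "median_reward_latency": reward_median,
    }


def summarize_behavior(trials: pd.DataFrame, window: int = 10) -> BehaviorSummary:
    """All session-level behavioral measures in one container."""
    _check_min_trials(trials)
    try:
        pi = perseveration_index(trials)
    except NotComputableError:
        pi = None
    moving = moving_strategy(trials, window)
    lat = latency_summaries(trials)
    return BehaviorSummary(
        p_better=float(trials["better_chosen"].mean()),
        p_better_trialwise=trials["better_chosen"].to_numpy(),
        win_stay=win_stay(trials),
        lose_shift=lose_shift(trials),
        perseveration_index=pi,
        flexibility_index=flexibility_index(trials),
        moving_ws=moving["moving_ws"],
        moving_ls=moving["moving_ls"],
        **lat,
    )
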