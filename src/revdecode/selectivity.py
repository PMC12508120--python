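"""Per-cell selectivity linear models and cross-validated heatmaps.

A neuron's per-trial epoch activity (the pre-choice bin mean, or the
retrieval-window mean) is regressed on trial labels: ``activity ~ 1 + side``
for chosen-side selectivity and ``activity ~ 1 + rewarded + side`` for
trial-outcome and reward-retrieval selectivity — side enters as a covariate
so side-selective neurons do not masquerade as outcome-selective.  A cell
is selective when the coefficient of interest has a two-sided p-value below
0.05 (uncorrected by design).  The session summary is the ratio of
selective cells over all imaged cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from revdecode.alignment import (
    EpochTensor,
    RawWindow,
    pre_event_bin,
    bin_before_offset,
)
from revdecode.decoding import TrialLabels
from revdecode.errors import ConfigurationError

__all__ = [
    "CellFit",
    "HeatmapMatrix",
    "fit_cell_glm",
    "selective_ratio",
    "session_selectivity",
    "peak_aligned_heatmap",
    "ALPHA",
]

#: Per-cell significance threshold (uncorrected).
ALPHA = 0.05

_EPOCHS = ("side", "outcome", "retrieval")


@dataclass
class CellFit:
    """One cell's selectivity model fit for one epoch."""

    cell: int
    epoch: str
    intercept: float
    beta_side: float
    beta_reward: float | None
    p_side: float
    p_reward: float | None
    selective: bool
    fittable: bool = True

    @property
    def beta_of_interest(self) -> float:
        return self.beta_side if self.epoch == "side" else self.beta_reward


@dataclass
class HeatmapMatrix:
    """Even-trial condition-difference traces, sorted by odd-trial fits.

    Values lie in [-1, 1] because each cell's per-condition averages are
    jointly range-normalized to [0, 1] before differencing.
    """

    values: np.ndarray  # cells x frames, sorted
    order: np.ndarray  # row -> original cell index
    peak_frames_odd: np.ndarray  # per original cell, 0-based peak of odd diff
    peak_frames_even: np.ndarray
    contrast: str


def fit_cell_glm(
    activity: np.ndarray,
    side: np.ndarray,
    rewarded: np.ndarray,
    epoch: str,
    cell: int = 0,
    alpha: float = ALPHA,
) -> CellFit:
    """Ordinary least-squares selectivity fit for one cell.

    ``side`` and ``rewarded`` are 0/1 per trial (L = 0).  Degenerate inputs
    (constant activity, rank-deficient design) return an unfittable,
    non-selective fit rather than raising: unfittable cells stay in the
    ratio denominator, which counts all imaged neurons.
    """
    if epoch not in _EPOCHS:
        raise ConfigurationError(f"unknown selectivity epoch {epoch!r}")
    activity = np.asarray(activity, float)
    side = np.asarray(side, float)
    rewarded = np.asarray(rewarded, float)
    if len(activity) < 3:
        raise ConfigurationError("need at least 3 trials")
    unfittable = CellFit(
        cell=cell, epoch=epoch, intercept=np.nan, beta_side=np.nan,
        beta_reward=None if epoch == "side" else np.nan,
        p_side=np.nan, p_reward=None if epoch == "side" else np.nan,
        selective=False, fittable=False,
    )
    if np.ptp(activity) == 0.0:
        return unfittable
    if epoch == "side":
        X = np.column_stack([np.ones_like(side), side])
        names = ["intercept", "side"]
    else:
        X = np.column_stack([np.ones_like(side), rewarded, side])
        names = ["intercept", "rewarded", "side"]
    if np.linalg.matrix_rank(X) < X.shape[1] or X.shape[0] <= X.shape[1]:
        return unfittable
    res = sm.OLS(activity, X).fit()
    params = dict(zip(names, res.params))
    pvals = dict(zip(names, res.pvalues))
    if epoch == "side":
        p_interest = pvals["side"]
    else:
        p_interest = pvals["rewarded"]
    return CellFit(
        cell=cell,
        epoch=epoch,
        intercept=params["intercept"],
        beta_side=params["side"],
        beta_reward=params.get("rewarded"),
        p_side=pvals["side"],
        p_reward=pvals.get("rewarded"),
        selective=bool(p_interest < alpha),
    )


def selective_ratio(fits: list) -> dict:
    """Session-level ratio of selective cells over all cells."""
    if len(fits) == 0:
        raise ConfigurationError("no cell fits")
    n_sel = sum(f.selective for f in fits)
    return {
        "n_cells": len(fits),
        "n_selective": n_sel,
        "ratio": n_sel / len(fits),
    }


def session_selectivity(
    choice_epoch: EpochTensor,
    retrieval_activity: np.ndarray,
    labels: TrialLabels,
    reward_delay: float = 1.0,
) -> dict:
    """Fit all three selectivity models for every cell of a session.

    Side and outcome use the same analysis bins as the decoder GLMs: side
    activity is the bin just before choice, outcome activity the bin just
    before the reward cue (choice + reward delay); retrieval activity is the
    precomputed reward-port window scalar (cells x trials).

    Returns ``{"fits": DataFrame, "ratios": DataFrame}``.
    """
    side01 = (labels.side == "R").astype(float)  # L = 0
    rew01 = (labels.outcome == "win").astype(float)
    b_side = pre_event_bin(choice_epoch)
    b_out = bin_before_offset(choice_epoch, reward_delay)
    activity = {
        "side": choice_epoch.values[:, b_side, :],
        "outcome": choice_epoch.values[:, b_out, :],
        "retrieval": np.asarray(retrieval_activity, float),
    }
    fit_rows = []
    ratio_rows = []
    for epoch_name, act in activity.items():
        fits = [
            fit_cell_glm(act[c], side01, rew01, epoch_name, cell=c)
            for c in range(act.shape[0])
        ]
        for f in fits:
            fit_rows.append(
                {
                    "cell": f.cell,
                    "epoch": f.epoch,
                    "intercept": f.intercept,
                    "beta_side": f.beta_side,
                    "beta_reward": f.beta_reward,
                    "p_side": f.p_side,
                    "p_reward": f.p_reward,
                    "selective": f.selective,
                    "fittable": f.fittable,
                }
            )
        row = selective_ratio(fits)
        row["epoch"] = epoch_name
        ratio_rows.append(row)
    return {
        "fits": pd.DataFrame(fit_rows),
        "ratios": pd.DataFrame(ratio_rows, columns=["epoch", "n_cells", "n_selective", "ratio"]),
    }


def _range_normalize(rows: np.ndarray) -> np.ndarray:
    """Jointly rescale a cell's condition-average traces to [0, 1].

    Constant traces map to all zeros.
    """
    lo = rows.min()
    hi = rows.max()
    if hi == lo:
        return np.zeros_like(rows)
    return (rows - lo) / (hi - lo)


def peak_aligned_heatmap(
    raw: RawWindow,
    labels: TrialLabels,
    contrast: str = "left-right",
    sort: str = "beta",
    betas: np.ndarray | None = None,
) -> HeatmapMatrix:
    """Cross-validated condition-difference heatmap.

    Trials are split by session order into odd and even halves.  Per cell
    and half, the two condition averages over the window are computed and
    jointly range-normalized to [0, 1]; the emitted rows are the even-half
    differences, while the peak index (extremum of the absolute difference)
    and row order are determined from the odd half — or from the signed
    selectivity betas if ``sort="beta"`` and ``betas`` is given (most
    negative first).
    """
    if contrast == "left-right":
        cond_a = labels.side == "L"
    elif contrast == "unrewarded-rewarded":
        cond_a = labels.outcome == "lose"
    else:
        raise ConfigurationError(f"unknown contrast {contrast!r}")
    cond_b = ~cond_a
    n_trials = raw.values.shape[2]
    odd = np.arange(n_trials) % 2 == 0  # 1-based odd trials
    for mask, name in ((cond_a, "A"), (cond_b, "B")):
        for half, hname in ((odd, "odd"), (~odd, "even")):
            if (mask & half).sum() < 2:
                raise ConfigurationError(
                    f"condition {name}/{hname}: fewer than 2 trials"
                )
    n_cells, n_frames, _ = raw.values.shape
    diffs = {}
    for hname, half in (("odd", odd), ("even", ~odd)):
        d = np.empty((n_cells, n_frames))
        for c in range(n_cells):
            avg_a = raw.values[c][:, cond_a & half].mean(axis=1)
            avg_b = raw.values[c][:, cond_b & half].mean(axis=1)
            normed = _range_normalize(np.vstack([avg_a, avg_b]))
            d[c] = normed[0] - normed[1]
        diffs[hname] = d
    peak_odd = np.argmax(np.abs(diffs["odd"]), axis=1)
    peak_even = np.argmax(np.abs(diffs["even"]), axis=1)
    if sort == "beta":
        if betas is None:
            raise ConfigurationError('sort="beta" requires betas')
        order = np.argsort(np.asarray(betas), kind="stable")
    elif sort == "peak":
        order = np.argsort(peak_odd, kind="stable")
    else:
        raise ConfigurationError(f"unknown sort {sort!r}")
    return HeatmapMatrix(
        values=diffs["even"][order],
        order=order,
        peak_frames_odd=peak_odd,
        peak_frames_even=peak_even,
        contrast=contrast,
    )
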