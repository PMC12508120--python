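"""Event-aligned epoch extraction and overlapping-bin temporal downsampling.

Windows of detrended fluorescence are cut around a named trial event (a 4 s
window centered on initiation, a 4 s window from 1 s before to 3 s after the
choice nosepoke, or a 1 s window centered on reward-port entry).  The
cells x frames x trials window tensor is then downsampled with overlapping
bins: bin 1 averages frames 1-6, bin 2 averages frames 3-9, and so on
(width 6 frames, stride 2, at 20 fps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from revdecode.errors import BoundsError, ConfigurationError, NotComputableError
from revdecode.traces import TraceMatrix

__all__ = [
    "EpochDefinition",
    "RawWindow",
    "EpochTensor",
    "extract_epoch",
    "bin_downsample",
    "pre_event_bin",
    "bin_before_offset",
    "retrieval_scalar_activity",
    "CHOICE_EPOCH",
    "INITIATION_EPOCH",
    "RETRIEVAL_EPOCH",
    "BIN_WIDTH",
    "BIN_STRIDE",
]

#: Overlapping-bin grid: each bin averages BIN_WIDTH frames, successive bins
#: start BIN_STRIDE frames apart.
BIN_WIDTH = 6
BIN_STRIDE = 2


@dataclass(frozen=True)
class EpochDefinition:
    """A named window relative to one trial-table timestamp."""

    name: str
    anchor_event: str  # a TrialTable timestamp column, e.g. "t_choice"
    window: tuple  # (start_offset, end_offset) seconds relative to anchor

    def __post_init__(self):
        if self.window[0] >= self.window[1]:
            raise ConfigurationError("window start must precede window end")


INITIATION_EPOCH = EpochDefinition("initiation", "t_init", (-2.0, 2.0))
CHOICE_EPOCH = EpochDefinition("choice", "t_choice", (-1.0, 3.0))
RETRIEVAL_EPOCH = EpochDefinition("retrieval", "t_retrieval", (-0.5, 0.5))


@dataclass
class RawWindow:
    """Frame-resolution window tensor, cells x frames x trials.

    ``anchor_frame`` is the 1-based index of the anchor frame within the
    window (identical for all trials by construction).
    """

    values: np.ndarray
    epoch: EpochDefinition
    anchor_frame: int
    fps: float
    trial_index_map: np.ndarray  # tensor slot -> TrialTable "index"


@dataclass
class EpochTensor:
    """Bin-resolution tensor, cells x bins x trials, plus the bin grid."""

    values: np.ndarray
    bin_centers: np.ndarray  # seconds relative to the anchor
    epoch: EpochDefinition
    anchor_frame: int  # 1-based frame index of the anchor within the raw window
    fps: float
    trial_index_map: np.ndarray

    @property
    def n_cells(self):
        return self.values.shape[0]

    @property
    def n_bins(self):
        return self.values.shape[1]

    @property
    def n_trials(self):
        return self.values.shape[2]

    def subset_cells(self, keep: np.ndarray) -> "EpochTensor":
        return EpochTensor(
            values=self.values[np.asarray(keep)],
            bin_centers=self.bin_centers,
            epoch=self.epoch,
            anchor_frame=self.anchor_frame,
            fps=self.fps,
            trial_index_map=self.trial_index_map,
        )

    def subset_trials(self, keep: np.ndarray) -> "EpochTensor":
        keep = np.asarray(keep)
        return EpochTensor(
            values=self.values[:, :, keep],
            bin_centers=self.bin_centers,
            epoch=self.epoch,
            anchor_frame=self.anchor_frame,
            fps=self.fps,
            trial_index_map=self.trial_index_map[keep],
        )


def _nearest_frame(t: np.ndarray, fps: float, t0: float) -> np.ndarray:
    """0-based index of the frame nearest to each time, ties toward earlier."""
    return np.ceil((np.asarray(t, float) - t0) * fps - 0.5).astype(int)


def extract_epoch(
    traces: TraceMatrix, trials: pd.DataFrame, epoch: EpochDefinition
) -> RawWindow:
    """Cut the epoch window around every trial's anchor event.

    The anchor maps to the nearest frame (ties toward the earlier frame);
    the window then spans ``round((end - start) * fps)`` frames starting
    ``round(start * fps)`` frames from the anchor.  A window that leaves the
    recorded trace raises :class:`BoundsError` naming the trial.
    """
    if epoch.anchor_event not in trials.columns:
        raise ConfigurationError(f"unknown anchor event {epoch.anchor_event!r}")
    t_anchor = trials[epoch.anchor_event].to_numpy(float)
    if np.isnan(t_anchor).any():
        bad = trials["index"].to_numpy()[np.isnan(t_anchor)][0]
        raise BoundsError(
            f"trial {bad}: anchor event {epoch.anchor_event!r} is undefined"
        )
    start_off, end_off = epoch.window
    n_frames_win = int(round((end_off - start_off) * traces.fps))
    anchor_idx = _nearest_frame(t_anchor, traces.fps, traces.t0)
    start_idx = anchor_idx + int(round(start_off * traces.fps))
    stop_idx = start_idx + n_frames_win
    bad = (start_idx < 0) | (stop_idx > traces.n_frames)
    if bad.any():
        trial_id = trials["index"].to_numpy()[bad][0]
        raise BoundsError(
            f"trial {trial_id}: epoch {epoch.name!r} window exceeds trace bounds"
        )
    n_trials = len(trials)
    out = np.empty((traces.n_cells, n_frames_win, n_trials))
    for k in range(n_trials):
        out[:, :, k] = traces.values[:, start_idx[k] : stop_idx[k]]
    anchor_frame = int(anchor_idx[0] - start_idx[0]) + 1  # 1-based, same all trials
    return RawWindow(
        values=out,
        epoch=epoch,
        anchor_frame=anchor_frame,
        fps=traces.fps,
        trial_index_map=trials["index"].to_numpy().copy(),
    )


def bin_downsample(raw: RawWindow) -> EpochTensor:
    """Overlapping-bin average: bin b = mean of frames 2b-1 .. 2b+4 (1-based)."""
    n_frames_win = raw.values.shape[1]
    if n_frames_win < BIN_WIDTH:
        raise ConfigurationError(
            f"window has {n_frames_win} frames; need >= {BIN_WIDTH}"
        )
    n_bins = (n_frames_win - BIN_WIDTH) // BIN_STRIDE + 1
    binned = np.empty((raw.values.shape[0], n_bins, raw.values.shape[2]))
    centers = np.empty(n_bins)
    for b in range(n_bins):
        lo = b * BIN_STRIDE
        hi = lo + BIN_WIDTH
        binned[:, b, :] = raw.values[:, lo:hi, :].mean(axis=1)
        # mean frame offset from the anchor frame, in seconds
        centers[b] = ((lo + hi - 1) / 2.0 - (raw.anchor_frame - 1)) / raw.fps
    return EpochTensor(
        values=binned,
        bin_centers=centers,
        epoch=raw.epoch,
        anchor_frame=raw.anchor_frame,
        fps=raw.fps,
        trial_index_map=raw.trial_index_map.copy(),
    )


def bin_before_offset(epoch: EpochTensor, offset_seconds: float = 0.0) -> int:
    """0-based index of the last bin whose frames all precede the anchor
    shifted by ``offset_seconds`` (e.g. 1.0 for the bin before the reward
    cue when the epoch is anchored at choice)."""
    ref_frame = epoch.anchor_frame + int(round(offset_seconds * epoch.fps))
    # 1-based bin b covers frames 2b-1 .. 2b+4; need 2b+4 < ref_frame
    b = (ref_frame - BIN_WIDTH + 1) // BIN_STRIDE
    b = min(b, epoch.n_bins)
    if b < 1:
        raise ConfigurationError(
            "no bin lies entirely before the reference event"
        )
    return b - 1


def pre_event_bin(epoch: EpochTensor) -> int:
    """0-based index of the largest bin entirely preceding the anchor frame."""
    if not (epoch.epoch.window[0] < 0.0):
        raise ConfigurationError("epoch window does not span the anchor")
    return bin_before_offset(epoch, 0.0)


def retrieval_scalar_activity(
    traces: TraceMatrix,
    trials: pd.DataFrame,
    half_width_frames: int = 10,
    reward_delay: float = 1.0,
) -> np.ndarray:
    """Per-trial scalar activity (cells x trials) around reward-port entry.

    Rewarded trials average the ``2 * half_width_frames`` frames centered on
    head entry (1 s at the default 10 frames / 20 fps).  Unrewarded trials
    use a same-width window at a pseudo-entry time: choice + reward delay +
    the session median reward latency.
    """
    rewarded = trials["rewarded"].to_numpy() == 1
    if not rewarded.any():
        raise NotComputableError(
            "no rewarded trials: pseudo-entry time undefined"
        )
    med = float(trials.loc[rewarded, "reward_latency"].median())
    t_entry = trials["t_retrieval"].to_numpy(float).copy()
    t_entry[~rewarded] = (
        trials["t_choice"].to_numpy(float)[~rewarded] + reward_delay + med
    )
    idx = _nearest_frame(t_entry, traces.fps, traces.t0)
    lo = idx - half_width_frames
    hi = idx + half_width_frames
    bad = (lo < 0) | (hi > traces.n_frames)
    if bad.any():
        trial_id = trials["index"].to_numpy()[bad][0]
        raise BoundsError(f"trial {trial_id}: retrieval window exceeds trace bounds")
    out = np.empty((traces.n_cells, len(trials)))
    for k in range(len(trials)):
        out[:, k] = traces.values[:, lo[k] : hi[k]].mean(axis=1)
    return out
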