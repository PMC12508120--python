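"""Forward model for detrended fluorescence traces with planted selectivity.

Each simulated neuron inserts a calcium transient (difference-of-exponentials
kernel, GCaMP6f-like: 0.05 s rise, 0.5 s decay) at one trial event — the
choice nosepoke, the reward cue (1 s after choice), or reward-port entry —
on every trial.  Selective cells gain amplitude on trials matching their
preferred condition (chosen side, or win/lose outcome); non-selective cells
carry only spontaneous transients and Gaussian noise.  Traces emulate
baseline-subtracted (not normalized) output of a source-extraction pipeline
sampled at 20 frames per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from revdecode.errors import BoundsError, ConfigurationError

__all__ = ["Cell", "CellPopulation", "TraceMatrix", "generate_traces", "calcium_kernel"]

_CLASSES = ("side", "outcome", "retrieval", "none")
_EVENTS = ("choice", "reward_cue", "retrieval")


@dataclass(frozen=True)
class Cell:
    """Generative parameters for one simulated neuron.

    ``modulation_depth`` is the fractional amplitude gain on preferred
    trials: the transient amplitude is
    ``base_amplitude * (1 + modulation_depth)`` when the trial matches
    ``preferred_condition`` and ``base_amplitude`` otherwise.

    ``onset_lead`` shifts the transient onset earlier than the locked event
    by that many seconds, emulating anticipatory ramping: choice-predictive
    frontal neurons are active before the choice nosepoke (which is what
    makes pre-choice decoding possible), and outcome-expectancy neurons
    before the reward cue.
    """

    selectivity_class: str = "none"
    preferred_condition: str | None = None  # L|R or win|lose
    locked_event: str = "choice"
    base_amplitude: float = 1.0
    modulation_depth: float = 0.0
    kernel_rise: float = 0.05
    kernel_decay: float = 0.5
    noise_sd: float = 0.1
    spontaneous_rate: float = 0.05
    onset_lead: float = 0.0

    def __post_init__(self):
        if self.selectivity_class not in _CLASSES:
            raise ConfigurationError(
                f"bad selectivity_class {self.selectivity_class!r}"
            )
        if self.locked_event not in _EVENTS:
            raise ConfigurationError(f"bad locked_event {self.locked_event!r}")
        if self.kernel_rise >= self.kernel_decay:
            raise ConfigurationError("kernel_rise must be < kernel_decay")
        if self.noise_sd < 0 or self.modulation_depth < 0:
            raise ConfigurationError("noise_sd and modulation_depth must be >= 0")
        if self.selectivity_class == "side" and self.preferred_condition not in (
            "L",
            "R",
        ):
            raise ConfigurationError("side cell needs preferred_condition L or R")
        if self.selectivity_class in ("outcome", "retrieval") and (
            self.preferred_condition not in ("win", "lose")
        ):
            raise ConfigurationError(
                f"{self.selectivity_class} cell needs preferred_condition win or lose"
            )


@dataclass
class CellPopulation:
    """An ordered list of :class:`Cell` making up one session's FOV."""

    cells: list = field(default_factory=list)

    def __len__(self):
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def __getitem__(self, i):
        return self.cells[i]

    def to_dict(self) -> dict:
        return {"cells": [asdict(c) for c in self.cells]}

    @classmethod
    def from_dict(cls, d: dict) -> "CellPopulation":
        return cls(cells=[Cell(**c) for c in d["cells"]])

    @classmethod
    def mixed(
        cls,
        n_cells: int,
        frac_side: float = 0.0,
        frac_outcome: float = 0.0,
        frac_retrieval: float = 0.0,
        modulation_depth: float = 2.0,
        noise_sd: float = 0.1,
        anticipation: float = 0.5,
        seed: int = 0,
        **kwargs,
    ) -> "CellPopulation":
        """Build a population with given fractions of planted selective cells.

        Counts are ``round(frac * n_cells)``; preferred conditions alternate
        deterministically (L/R, win/lose) so both labels are represented.
        The remainder are non-selective noise cells.  Cell order is shuffled
        with ``seed`` so selectivity class is not confounded with cell index.
        Side and outcome cells get ``anticipation`` seconds of onset lead so
        their signal is readable in the bins just before choice and reward
        cue; retrieval cells respond at port entry itself.
        """
        n_side = round(frac_side * n_cells)
        n_out = round(frac_outcome * n_cells)
        n_ret = round(frac_retrieval * n_cells)
        if n_side + n_out + n_ret > n_cells:
            raise ConfigurationError("selective fractions exceed 1")
        cells = []
        for i in range(n_side):
            cells.append(
                Cell(
                    "side",
                    "L" if i % 2 == 0 else "R",
                    "choice",
                    modulation_depth=modulation_depth,
                    noise_sd=noise_sd,
                    onset_lead=anticipation,
                    **kwargs,
                )
            )
        for i in range(n_out):
            cells.append(
                Cell(
                    "outcome",
                    "win" if i % 2 == 0 else "lose",
                    "reward_cue",
                    modulation_depth=modulation_depth,
                    noise_sd=noise_sd,
                    onset_lead=anticipation,
                    **kwargs,
                )
            )
        for i in range(n_ret):
            cells.append(
                Cell(
                    "retrieval",
                    "win" if i % 2 == 0 else "lose",
                    "retrieval",
                    modulation_depth=modulation_depth,
                    noise_sd=noise_sd,
                    **kwargs,
                )
            )
        while len(cells) < n_cells:
            cells.append(Cell("none", None, "choice", noise_sd=noise_sd, **kwargs))
        order = np.random.default_rng(seed).permutation(n_cells)
        return cls(cells=[cells[i] for i in order])


@dataclass
class TraceMatrix:
    """Detrended fluorescence, cells x frames, at a fixed sampling rate."""

    values: np.ndarray
    fps: float = 20.0
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be 2-D (cells x frames)")
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fps


def calcium_kernel(rise: float, decay: float, fps: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1.

    Truncated where the decay envelope falls below 1% of its peak.
    """
    t_end = decay * np.log(100.0)
    t = np.arange(0.0, t_end, 1.0 / fps)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:
        raise ConfigurationError("degenerate kernel")
    return k / peak


def _event_times(trials: pd.DataFrame, locked_event: str, reward_delay: float):
    """Per-trial anchor time for a cell's locked event.

    The reward-cue moment exists on every trial (choice + reward delay) even
    though the cue lights only on rewarded trials; lose-preferring outcome
    cells respond at that moment on unrewarded trials.  Retrieval events on
    unrewarded trials use a pseudo-entry at choice + delay + the session
    median reward latency.
    """
    if locked_event == "choice":
        return trials["t_choice"].to_numpy(float)
    if locked_event == "reward_cue":
        return trials["t_choice"].to_numpy(float) + reward_delay
    med = trials.loc[trials["rewarded"] == 1, "reward_latency"].median()
    if np.isnan(med):
        med = 1.0  # no rewarded trials: fall back to the latency-model median
    t = trials["t_retrieval"].to_numpy(float).copy()
    missing = np.isnan(t)
    t[missing] = trials["t_choice"].to_numpy(float)[missing] + reward_delay + med
    return t


def _preferred_mask(trials: pd.DataFrame, cell: Cell) -> np.ndarray:
    if cell.selectivity_class == "none" or cell.preferred_condition is None:
        return np.zeros(len(trials), dtype=bool)
    if cell.selectivity_class == "side":
        return (trials["chosen_side"] == cell.preferred_condition).to_numpy()
    want_win = cell.preferred_condition == "win"
    return (trials["rewarded"] == 1).to_numpy() == want_win


def generate_traces(
    trials: pd.DataFrame,
    cells: CellPopulation,
    session_duration: float,
    seed: int,
    fps: float = 20.0,
    reward_delay: float = 1.0,
) -> TraceMatrix:
    """Render the population's fluorescence for one session.

    Deterministic given ``seed``; each cell draws from its own child stream,
    and amplitude scaling does not perturb the random draws (the noise-free
    component is linear in ``base_amplitude``).
    """
    t_events_max = float(
        np.nanmax(
            trials[["t_init_cue", "t_init", "t_choice", "t_reward_cue", "t_retrieval"]]
            .to_numpy(float)
        )
    )
    if t_events_max >= session_duration:
        raise BoundsError(
            f"trial event at t={t_events_max:.2f}s is beyond "
            f"session_duration={session_duration:.2f}s"
        )
    n_frames = int(round(session_duration * fps))
    out = np.zeros((len(cells), n_frames))
    children = np.random.SeedSequence(seed).spawn(len(cells))
    for ci, (cell, child) in enumerate(zip(cells, children)):
        rng = np.random.default_rng(child)
        kernel = calcium_kernel(cell.kernel_rise, cell.kernel_decay, fps)
        row = out[ci]
        # evoked transients, onset optionally leading the locked event
        times = _event_times(trials, cell.locked_event, reward_delay) - cell.onset_lead
        amps = cell.base_amplitude * (
            1.0 + cell.modulation_depth * _preferred_mask(trials, cell)
        )
        # spontaneous transients: homogeneous Poisson over the session
        n_spont = rng.poisson(cell.spontaneous_rate * session_duration)
        spont_times = rng.uniform(0.0, session_duration, n_spont)
        all_times = np.concatenate([times, spont_times])
        all_amps = np.concatenate(
            [amps, np.full(n_spont, cell.base_amplitude)]
        )
        for t_ev, a in zip(all_times, all_amps):
            if a == 0.0:
                continue
            start = int(np.round(t_ev * fps))
            k0 = max(0, -start)  # onset lead can precede recording start
            start = max(start, 0)
            stop = min(start + len(kernel) - k0, n_frames)
            if start >= n_frames or stop <= start:
                continue
            row[start:stop] += a * kernel[k0 : k0 + stop - start]
        if cell.noise_sd > 0:
            row += rng.normal(0.0, cell.noise_sd, n_frames)
    return TraceMatrix(values=out, fps=fps, t0=0.0)
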