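"""Balanced leave-one-trial-out linear decoding of choice and outcome.

For every held-out trial, the remaining trials are balanced so the training
set holds the same number of left-rewarded, left-unrewarded, right-rewarded
and right-unrewarded trials (the within-session minimum after excluding the
test trial), resampled afresh for every test trial.  A linear-kernel
maximum-margin classifier (SVM) is trained per time bin on the balanced set
and scored 1/0 on the held-out trial; per-bin accuracy is the mean over
trials.  Chance is estimated by rerunning the whole procedure with the
label sequence circularly shifted by a random nonzero offset, and the link
to single cells by ablating the cells with the largest absolute decoder
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from revdecode.alignment import EpochTensor, pre_event_bin
from revdecode.errors import ConfigurationError, SessionNotDecodableError

__all__ = [
    "TrialLabels",
    "DecoderResult",
    "make_labels",
    "balanced_train_indices",
    "loo_decode",
    "shuffle_null",
    "ablation_curve",
    "CONDITIONS",
]

#: The four side x outcome conditions balanced in every training set.
CONDITIONS = ("LW", "LU", "RW", "RU")


@dataclass
class TrialLabels:
    """Per-trial side ("L"/"R"), outcome ("win"/"lose") and their cross."""

    side: np.ndarray
    outcome: np.ndarray

    def __post_init__(self):
        self.side = np.asarray(self.side)
        self.outcome = np.asarray(self.outcome)
        if self.side.shape != self.outcome.shape:
            raise ConfigurationError("side and outcome must have equal length")

    def __len__(self):
        return len(self.side)

    @property
    def condition(self) -> np.ndarray:
        return np.char.add(
            self.side.astype(str),
            np.where(self.outcome == "win", "W", "U"),
        )

    def target(self, which: str) -> np.ndarray:
        if which == "side":
            return self.side
        if which == "outcome":
            return self.outcome
        raise ConfigurationError(f"unknown decoding target {which!r}")

    def shifted(self, offset: int) -> "TrialLabels":
        """Labels circularly shifted by ``offset`` trials (jointly)."""
        return TrialLabels(
            side=np.roll(self.side, offset), outcome=np.roll(self.outcome, offset)
        )

    def permuted(self, order: np.ndarray) -> "TrialLabels":
        return TrialLabels(side=self.side[order], outcome=self.outcome[order])


def make_labels(trials: pd.DataFrame) -> TrialLabels:
    """Derive decoding labels from a trial table."""
    side = trials["chosen_side"].to_numpy(str)
    outcome = np.where(trials["rewarded"].to_numpy() == 1, "win", "lose")
    return TrialLabels(side=side, outcome=outcome)


@dataclass
class DecoderResult:
    """Per-bin leave-one-out decoding output for one session and target."""

    target: str
    accuracy: np.ndarray  # per decoded bin, in [0, 1]
    correctness: np.ndarray  # trials x decoded bins, 0/1
    weights: np.ndarray  # cells x decoded bins, mean over folds
    bins: np.ndarray  # 0-based bin indices into the epoch tensor
    bin_centers: np.ndarray  # seconds relative to the anchor
    shuffle_accuracy: np.ndarray | None = None
    n_shuffle: int = 0
    per_condition_train_count: int = 0
    anchor_frame: int = 0
    fps: float = 20.0

    def accuracy_at(self, bin_index: int) -> float:
        """Accuracy at an epoch-tensor bin index (must have been decoded)."""
        pos = np.flatnonzero(self.bins == bin_index)
        if len(pos) == 0:
            raise ConfigurationError(f"bin {bin_index} was not decoded")
        return float(self.accuracy[pos[0]])


def _condition_indices(labels: TrialLabels) -> dict:
    cond = labels.condition
    return {c: np.flatnonzero(cond == c) for c in CONDITIONS}


def _check_conditions(labels: TrialLabels) -> None:
    counts = {c: len(ix) for c, ix in _condition_indices(labels).items()}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise SessionNotDecodableError(
            f"session not decodable: empty condition(s) {empty} "
            f"(counts {counts})"
        )


def balanced_train_indices(
    labels: TrialLabels,
    test_trial: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Balanced training trials for one fold.

    Draws ``m`` trials without replacement from each of the four conditions,
    where ``m`` is the minimum condition count after excluding the test
    trial; the test trial itself is never included.  A fresh draw is made
    per (test trial, seed).
    """
    if not (0 <= test_trial < len(labels)):
        raise ConfigurationError(f"test_trial {test_trial} out of range")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed), test_trial]))
    )
    by_cond = {
        c: ix[ix != test_trial] for c, ix in _condition_indices(labels).items()
    }
    counts = {c: len(ix) for c, ix in by_cond.items()}
    if min(counts.values()) == 0:
        empty = [c for c, n in counts.items() if n == 0]
        raise SessionNotDecodableError(
            f"session not decodable: empty condition(s) {empty} after "
            f"excluding test trial {test_trial}"
        )
    m = min(counts.values())
    picked = [rng.choice(ix, size=m, replace=False) for ix in by_cond.values()]
    return np.sort(np.concatenate(picked))


def loo_decode(
    epoch: EpochTensor,
    labels: TrialLabels,
    target: str = "side",
    seed: int = 0,
    bins: np.ndarray | None = None,
    C: float = 1.0,
) -> DecoderResult:
    """Leave-one-trial-out balanced decoding at each requested bin.

    All bins of one fold share the same balanced training set (trials are
    balanced once per held-out trial, not per bin).  ``bins`` restricts the
    decoded bins (default: all); inputs are used unscaled, as detrended
    fluorescence is already on a common baseline.
    """
    if epoch.n_cells < 1:
        raise ConfigurationError("need at least one cell")
    if len(labels) != epoch.n_trials:
        raise ConfigurationError("labels and epoch tensor disagree on trials")
    _check_conditions(labels)
    bins = np.arange(epoch.n_bins) if bins is None else np.asarray(bins, int)
    y_all = labels.target(target)
    classes = np.unique(y_all)
    n_trials = epoch.n_trials
    correctness = np.zeros((n_trials, len(bins)), dtype=int)
    weights = np.zeros((epoch.n_cells, len(bins)))
    m_min = None
    for t in range(n_trials):
        fold_rng = np.random.default_rng(np.random.SeedSequence([int(seed), t]))
        train = balanced_train_indices(labels, t, fold_rng)
        m = len(train) // 4
        m_min = m if m_min is None else min(m_min, m)
        y_train = y_all[train]
        for j, b in enumerate(bins):
            X_train = epoch.values[:, b, train].T
            x_test = epoch.values[:, b, t][None, :]
            clf = SVC(kernel="linear", C=C)
            clf.fit(X_train, y_train)
            score = float(clf.decision_function(x_test)[0])
            if score == 0.0:  # point exactly on the hyperplane: fair coin
                pred = classes[int(fold_rng.random() < 0.5)]
            else:
                pred = clf.classes_[int(score > 0)]
            correctness[t, j] = int(pred == y_all[t])
            weights[:, j] += clf.coef_[0]
    weights /= n_trials
    return DecoderResult(
        target=target,
        accuracy=correctness.mean(axis=0),
        correctness=correctness,
        weights=weights,
        bins=bins,
        bin_centers=epoch.bin_centers[bins],
        per_condition_train_count=int(m_min),
        anchor_frame=epoch.anchor_frame,
        fps=epoch.fps,
    )


def shuffle_null(
    epoch: EpochTensor,
    labels: TrialLabels,
    target: str = "side",
    n_shuffle: int = 100,
    seed: int = 0,
    bins: np.ndarray | None = None,
    C: float = 1.0,
    method: str = "shift",
) -> np.ndarray:
    """Chance-level accuracy from label-shuffled reruns of the decoder.

    Each repeat circularly shifts the joint label sequence by a uniform
    random offset in [1, N-1] (``method="shift"``, preserving label
    autocorrelation) or fully permutes it (``method="permute"``), reruns the
    full leave-one-out decode, and the per-bin accuracies are averaged over
    repeats.
    """
    if n_shuffle < 1:
        raise ConfigurationError("n_shuffle must be >= 1")
    if method not in ("shift", "permute"):
        raise ConfigurationError(f"unknown shuffle method {method!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F]))
    n = len(labels)
    acc = []
    for r in range(n_shuffle):
        if method == "shift":
            offset = int(rng.integers(1, n))
            lab = labels.shifted(offset)
        else:
            lab = labels.permuted(rng.permutation(n))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = loo_decode(epoch, lab, target=target, seed=sub_seed, bins=bins, C=C)
        acc.append(res.accuracy)
    return np.mean(acc, axis=0)


def ablation_curve(
    epoch: EpochTensor,
    labels: TrialLabels,
    target: str = "side",
    ks: list | None = None,
    seed: int = 0,
    at_bin: int | None = None,
    C: float = 1.0,
) -> np.ndarray:
    """Accuracy at the pre-event bin after removing top-|weight| cells.

    Cells are ranked by the absolute decoder weight at ``at_bin`` (default:
    the bin just before the anchor event) from a full-population decode;
    for each ``k`` the top-k cells are removed and the decoder rerun on the
    remainder.  ``k = 0`` reproduces the baseline accuracy.
    """
    ks = [0, 5, 10] if ks is None else list(ks)
    if max(ks) >= epoch.n_cells:
        raise ConfigurationError(
            f"cannot ablate {max(ks)} of {epoch.n_cells} cells"
        )
    b = pre_event_bin(epoch) if at_bin is None else int(at_bin)
    base = loo_decode(epoch, labels, target=target, seed=seed, bins=np.array([b]), C=C)
    order = np.argsort(-np.abs(base.weights[:, 0]), kind="stable")
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        if k == 0:
            out[i] = base.accuracy[0]
            continue
        keep = np.setdiff1d(np.arange(epoch.n_cells), order[:k])
        res = loo_decode(
            epoch.subset_cells(keep), labels, target=target, seed=seed,
            bins=np.array([b]), C=C,
        )
        out[i] = res.accuracy[0]
    return out
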