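"""Session- and trial-level design matrices and GLM fitting.

Two families of models are supported: binomial learning models of the
trial-wise better-choice indicator (predictors TrialNum, Block, Schedule,
Session, Area, and for chemogenetic designs Drug and Order), and Gaussian
models of per-session decoding accuracy at the pre-event bin (predictors
Area, Schedule, Session, ensemble size, Win-Stay, Lose-Shift, Perseveration
and Flexibility indices, latency medians, with Area interactions for the
strategy indices).  Codings follow the convention 0 = female / 1 = male,
0 = OFC / 1 = M2, 0 = vehicle / 1 = CNO.

Fitting is delegated to statsmodels; the contract of this module is design
construction and result packaging, not a bespoke estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from revdecode.alignment import BIN_STRIDE, BIN_WIDTH
from revdecode.behavior import BehaviorSummary
from revdecode.decoding import DecoderResult
from revdecode.errors import ConfigurationError, RankDeficiencyError

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "build_choice_design",
    "build_accuracy_design",
    "fit_glm",
    "SessionMeta",
]

_BINARY_CODINGS = {
    "Sex": {"F": 0, "M": 1, 0: 0, 1: 1},
    "Area": {"OFC": 0, "M2": 1, 0: 0, 1: 1},
    "Drug": {"VEH": 0, "CNO": 1, 0: 0, 1: 1},
}


@dataclass(frozen=True)
class SessionMeta:
    """Per-session metadata needed by the design builders."""

    subject: str
    area: str | int  # "OFC"/"M2" or 0/1
    schedule: int
    session: int
    sex: str | int | None = None
    drug: str | int | None = None
    order: int | None = None


def _code(name: str, value):
    coding = _BINARY_CODINGS[name]
    if value not in coding:
        raise ConfigurationError(f"bad {name} value {value!r}")
    return coding[value]


@dataclass
class DesignMatrix:
    """Aligned response, predictors and random-effect grouping."""

    response: np.ndarray
    predictors: pd.DataFrame
    groups: np.ndarray
    family: str  # "binomial" | "gaussian"

    def __post_init__(self):
        n = len(self.response)
        if len(self.predictors) != n or len(self.groups) != n:
            raise ConfigurationError("response/predictors/groups row mismatch")
        for name in ("Sex", "Area", "Drug"):
            if name in self.predictors.columns:
                vals = set(np.unique(self.predictors[name]))
                if not vals <= {0, 1}:
                    raise ConfigurationError(
                        f"{name} column must be coded 0/1, got {sorted(vals)}"
                    )


@dataclass
class GlmFit:
    """Packaged GLM output: coefficient table and convergence state."""

    family: str
    formula: str
    coefficients: pd.DataFrame  # index = term; columns beta, se, z, p
    converged: bool
    random_intercept: bool
    n_obs: int

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "beta"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def build_choice_design(
    sessions: list[tuple[pd.DataFrame, SessionMeta]]
) -> DesignMatrix:
    """Trial-level binomial design: response is the better-choice indicator."""
    if not sessions:
        raise ConfigurationError("no sessions")
    resp, rows, groups = [], [], []
    for trials, meta in sessions:
        n = len(trials)
        area = _code("Area", meta.area)
        for t in range(n):
            row = {
                "TrialNum": t + 1,
                "Block": int(trials["block"].iloc[t]),
                "Schedule": meta.schedule,
                "Session": meta.session,
                "Area": area,
            }
            if meta.drug is not None:
                row["Drug"] = _code("Drug", meta.drug)
            if meta.order is not None:
                row["Order"] = meta.order
            if meta.sex is not None:
                row["Sex"] = _code("Sex", meta.sex)
            rows.append(row)
            groups.append(meta.subject)
        resp.extend(trials["better_chosen"].tolist())
    return DesignMatrix(
        response=np.asarray(resp, float),
        predictors=pd.DataFrame(rows),
        groups=np.asarray(groups),
        family="binomial",
    )


def _target_bin_accuracy(
    result: DecoderResult, target: str, reward_delay: float
) -> float:
    """Session accuracy at the analysis bin for a given decoding target.

    Chosen-side models use the bin just before choice; trial-outcome models
    the bin just before the reward cue (choice + reward delay, the moment
    the pellet is signaled).
    """
    offset = 0.0 if target == "side" else reward_delay
    ref_frame = result.anchor_frame + int(round(offset * result.fps))
    b = (ref_frame - BIN_WIDTH + 1) // BIN_STRIDE - 1  # 0-based
    if b < 0:
        raise ConfigurationError("no bin precedes the reference event")
    return result.accuracy_at(b)


def build_accuracy_design(
    decoder_results: list[DecoderResult],
    behavior_summaries: list[BehaviorSummary],
    metadata: list[SessionMeta],
    n_cells: list[int],
    target: str = "side",
    reward_delay: float = 1.0,
    area_interactions: bool = True,
) -> DesignMatrix:
    """Session-level Gaussian design for decoding accuracy.

    One row per session; response is accuracy at the target's pre-event
    bin.  Strategy indices gain ``Area:<name>`` interaction columns when
    ``area_interactions`` (dropped automatically at fit time if constant).
    """
    if not (
        len(decoder_results) == len(behavior_summaries) == len(metadata) == len(n_cells)
    ):
        raise ConfigurationError("mismatched session lists")
    resp, rows, groups = [], [], []
    for res, beh, meta, nc in zip(
        decoder_results, behavior_summaries, metadata, n_cells
    ):
        resp.append(_target_bin_accuracy(res, target, reward_delay))
        area = _code("Area", meta.area)
        row = {
            "Area": area,
            "Schedule": meta.schedule,
            "Session": meta.session,
            "NumCells": nc,
            "WS": beh.win_stay,
            "LS": beh.lose_shift,
            "PerseverationIndex": (
                np.nan
                if beh.perseveration_index is None
                else beh.perseveration_index
            ),
            "FlexibilityIndex": beh.flexibility_index,
            "InitLatency": beh.median_init_latency,
            "ChoiceLatency": beh.median_choice_latency,
            "RewardLatency": (
                np.nan
                if beh.median_reward_latency is None
                else beh.median_reward_latency
            ),
        }
        if area_interactions:
            for name in ("WS", "LS", "PerseverationIndex", "FlexibilityIndex"):
                row[f"Area:{name}"] = area * row[name]
        rows.append(row)
        groups.append(meta.subject)
    return DesignMatrix(
        response=np.asarray(resp, float),
        predictors=pd.DataFrame(rows),
        groups=np.asarray(groups),
        family="gaussian",
    )


def fit_glm(
    design: DesignMatrix,
    family: str | None = None,
    random_intercept: bool = False,
) -> GlmFit:
    """Maximum-likelihood GLM fit with an intercept.

    Constant predictor columns (other than the added intercept) are dropped;
    a remaining rank deficiency (e.g. duplicated predictors) raises
    :class:`RankDeficiencyError`.  With ``random_intercept`` and at least
    three subjects, Gaussian models fit a subject random intercept
    (linear mixed model); binomial models use subject-clustered robust
    standard errors.  Fewer than three subjects falls back to fixed
    effects.
    """
    family = family or design.family
    if family not in ("binomial", "gaussian"):
        raise ConfigurationError(f"unknown family {family!r}")
    X = design.predictors.copy()
    dropped = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    X = X.drop(columns=dropped)
    keep = ~X.isna().any(axis=1) & ~pd.isna(design.response)
    X = X.loc[keep]
    y = design.response[keep.to_numpy()]
    groups = design.groups[keep.to_numpy()]
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise RankDeficiencyError(
            f"design is rank deficient; columns: {list(exog.columns)}"
        )
    n_subjects = len(np.unique(groups))
    use_re = random_intercept and n_subjects >= 3
    formula = f"response ~ 1 + {' + '.join(X.columns)}"
    if use_re and family == "gaussian":
        model = sm.MixedLM(y, exog, groups=groups)
        res = model.fit(reml=True)
        terms = list(exog.columns)
        coef = pd.DataFrame(
            {
                "beta": res.params[terms],
                "se": res.bse[terms],
                "z": res.tvalues[terms],
                "p": res.pvalues[terms],
            }
        )
        converged = bool(res.converged)
    else:
        fam = (
            sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
        )
        model = sm.GLM(y, exog, family=fam)
        if use_re:  # binomial: cluster-robust SEs by subject
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit()
        coef = pd.DataFrame(
            {
                "beta": res.params,
                "se": res.bse,
                "z": res.tvalues,
                "p": res.pvalues,
            }
        )
        converged = bool(getattr(res, "converged", True))
    coef.index.name = "term"
    return GlmFit(
        family=family,
        formula=formula,
        coefficients=coef,
        converged=converged,
        random_intercept=use_re,
        n_obs=len(y),
    )
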