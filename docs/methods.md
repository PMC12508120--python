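# Methods

## Task and agent simulation

A session is three blocks of committed trials (default 75 per block); the
better side reverses at each block boundary and the reward-probability
ratio becomes more uncertain in block 3 (schedule 1: 100:0, 100:0, 90:10;
schedule 2: 90:10, 90:10, 80:20; schedule 3: 80:20, 80:20, 70:30, with the
better side alternating L/R). Event timing per trial: initiation cue →
initiation touch (deadline 40 s) → choice nosepoke (deadline 60 s) →
reward cue 1 s after choice on rewarded trials → reward-port entry; a 5 s
timeout follows unrewarded choices, and a 10 s ITI separates trials.
Omissions are not simulated: every generated trial is a committed trial,
which is the unit of all downstream analyses.

Choices come from one of three agents:

- **wsls** — after a win, repeat the previous side with probability
  `p_stay_after_win` (default 0.8); after a loss, switch with probability
  `p_shift_after_loss` (default 0.7); first trial uniform. Setting both
  parameters to 0.5 gives an indifferent agent whose choices are iid —
  the correct control for chance-calibration experiments (see below).
- **q_learning** — per-side values updated by `V ← V + α(r − V)` on the
  chosen side (α default 0.3) and a softmax over the value difference with
  inverse temperature β (default 5).
- **forced_better** — always chooses the currently better side; used to
  measure schedule contingencies, not a behavioral model.

The two parametric families span the low/high Win-Stay–Lose-Shift regimes
needed for strategy-accuracy regressions. Latencies are log-normal per
type (defaults: initiation `exp(N(log 2, 0.6²))` s, choice
`exp(N(log 1.5, 0.6²))` s, reward `exp(N(log 1, 0.5²))` s) — strictly
positive and right-skewed, as operant latencies are — clipped at the
respective deadline. All randomness flows through one seed per call;
sub-streams are spawned deterministically, so identical inputs give
byte-identical sessions.

## Fluorescence forward model

Traces emulate detrended (baseline-subtracted, not normalized) output of a
1-photon source-extraction pipeline at 20 fps. Each cell inserts a
difference-of-exponentials transient (rise 0.05 s, decay 0.5 s,
GCaMP6f-like; peak-normalized, truncated at 1% of peak) at its locked
event on every trial: the choice nosepoke, the reward-cue moment
(choice + 1 s — defined on every trial even though the cue lights only on
rewarded ones), or reward-port entry (on unrewarded trials, a pseudo-entry
at choice + delay + the session median reward latency). The amplitude is
`base × (1 + depth)` on trials matching the cell's preferred condition
(chosen side, or win/lose) and `base` otherwise, so the noise-free trace
is linear in `base_amplitude`. Spontaneous transients arrive as a
homogeneous Poisson process (default 0.05 events/s) at `base` amplitude,
plus iid Gaussian noise (default SD 0.1).

**Anticipatory onset.** A transient that starts *at* the choice nosepoke
leaves no trace in a bin that ends before the nosepoke, yet
choice-predictive frontal neurons are active before the movement — choice
decoding empirically ramps up before trial initiation. The forward model
therefore exposes `onset_lead`: the transient onset precedes the locked
event by that many seconds. `CellPopulation.mixed` defaults to 0.5 s for
side and outcome cells (so their signal is readable in the analysis bins
just before choice and reward cue) and 0 for retrieval cells, which
respond at port entry itself.

What the generator does **not** emulate: slow drift and neuropil
contamination, trial-to-trial amplitude variability, correlated noise
across cells, sub-Poisson event statistics, and mixed selectivity. Tests
passing on these traces show the analysis chain is correct and calibrated
under its stated assumptions, not that any particular biological claim
holds in real recordings.

## Alignment

Epoch windows: initiation (−2 s, +2 s), choice (−1 s, +3 s), retrieval
(−0.5 s, +0.5 s), each anchored at the nearest frame to the event time
(ties toward the earlier frame — deterministic under sub-frame
timestamps). Downsampling uses overlapping bins of 6 frames with stride 2
(bin 1 = frames 1–6, bin 2 = frames 3–9, …; an 80-frame window gives 38
bins); where a 5-frame bin has also been described for the same analysis,
the 6-frame definition is used throughout. The analysis bin for a given
event is the last bin whose frames all precede it: bin 8 for the choice
nosepoke in the choice epoch, bin 18 for the reward cue. The retrieval
scalar averages the 20 frames (1 s) centered on port entry; a 0.5 s
half-window is exposed as an option. The anchoring of the unrewarded-trial
"corresponding window" is not uniquely determined by its verbal
description; we center it at choice + reward delay + the session median
reward latency, which matches the center of the rewarded-trial entry-time
distribution.

## Decoding

Per time bin and held-out trial: balance the remaining trials to *m* per
side × outcome condition (*m* = the within-session minimum after excluding
the test trial — the alternative of a fixed cross-session *m* would
discard sessions; the minimum rule uses every session that has all four
conditions), drawn freshly per test trial from a seed hashed with the
test-trial index so all bins of a fold share one balanced set (trials are
balanced, not bins). The classifier is a linear-kernel SVM with unit box
constraint (the common default of SVM implementations) and no feature
scaling — inputs are already detrended and on a common baseline. A test
point exactly on the hyperplane is resolved by a fair coin from the fold's
stream. Sessions with an empty condition raise a typed error rather than
silently unbalancing; callers may restrict to blocks where both outcomes
occur.

The shuffle null circularly shifts the joint label sequence by a uniform
offset in [1, N−1] — preserving label autocorrelation, which a full
permutation (also provided) destroys — and averages accuracies over
repeats (default 100; calibration tests use 20). The ablation analysis
ranks cells by |mean decoder weight| at the pre-event bin and reruns the
decoder with the top-k removed.

**Chance is 0.5 only for structureless labels.** With a behaviorally
realistic agent, label sequences are imbalanced and autocorrelated, and
per-session accuracy on signal-free traces is overdispersed relative to
Binomial(N, 0.5): sparse spontaneous transients make most test points lie
near the origin, where the SVM's prediction is a session-specific accident
that interacts with label imbalance. This is precisely why the analysis
carries its own shuffled-label null. Chance-calibration experiments
therefore use the indifferent agent, for which the binomial reference is
exact.

## Selectivity

Activity scalars are the decoder's analysis bins (pre-choice bin for side,
pre-reward-cue bin for outcome) and the retrieval window scalar. Models
are ordinary least squares with identity link: `γ ~ 1 + side` (side) and
`γ ~ 1 + rewarded + side` (outcome, retrieval); side enters as a covariate
so side-selective cells do not masquerade as outcome- or
retrieval-selective when side and reward are correlated within a session.
Two-sided t-distribution p-values; α = 0.05, uncorrected by design. Cells
with constant activity or a rank-deficient design are *unfittable* and
counted as non-selective in the ratio denominator (the denominator is all
imaged neurons). Side and reward are coded 0/1 with L = 0; any consistent
0/1 coding gives identical p-values.

Peak-aligned heatmaps split trials by session order into odd/even halves;
per cell and half, the two condition averages are jointly range-normalized
to [0, 1] (a constant cell maps to zeros) and differenced, bounding values
in [−1, 1]. Peak indices and row order come from the odd half — sorted by
signed selectivity beta by default, by odd-half peak index as an option
(both orderings are in common use) — and the even half is displayed.

## Session-level models

The choice model is a binomial GLM of the trial-wise better-choice
indicator on TrialNum (1..N within session; N = 225 under defaults),
Block, Schedule, Session, Area, and, for chemogenetic designs, Drug and
Order. The accuracy model is Gaussian on per-session decoding accuracy at
the target's analysis bin, with Area, Schedule, Session, ensemble size,
Win-Stay, Lose-Shift, Perseveration and Flexibility indices, latency
medians, and Area interactions for the strategy indices. Constant columns
are dropped before fitting; a residual rank deficiency is a typed error.
With at least three subjects and `random_intercept=True`, Gaussian models
fit a subject random intercept (linear mixed model, REML); binomial models
use a fixed-effects GLM with subject-clustered robust standard errors,
since no frequentist binomial random-intercept GLMM is available in the
underlying statistics library; with fewer subjects both fall back to fixed
effects.

## Behavioral metrics

Win-Stay (Lose-Shift) is the count of trials whose predecessor was
rewarded (unrewarded) and whose side repeats (changes), divided by N − 1 —
"proportion of all trials"; the conventional conditional proportion
(divide by post-win or post-loss trials) is available behind a flag. The
Perseveration Index averages, over unrewarded trials that begin a loss run
on a side, the number of trials until the side changes; runs unresolved at
session end are censored at the remaining trial count rather than dropped
(dropping would bias the index downward); the censoring is configurable.
Moving strategy traces average the per-trial WS/LS indicator over the
`window` (default 10) nearest trials, the window sliding inward at the
session edges so it always covers `window` trials (with `window ≥ N` every
entry is the session proportion). Latency summaries are per-session
medians; the reward median covers rewarded trials only.

## Problem sizes and numerical choices

Simulation-based tests use sessions of 60–120 trials with 12–40 cells and
10–20 seeded replicates, and Monte-Carlo checks pool 9,000–10,000 trials —
sizes at which binomial confidence intervals are tight enough to be
informative while the full suite stays fast. Recovery experiments plant
modulation depth 3 (strong, for detection-rate checks) or depths in
[0.02, 0.3] (the dynamic range over which leave-one-out accuracy spans
~0.55–0.95 at 20 cells, used when accuracy must *vary* across sessions,
as in the strategy-regression cohort). Selectivity calibration uses 1,000
null cells per model. All tolerances in tests are binomial CIs at the
stated n or fixed absolute bands stated alongside the planted truth.

## Known limitations

- The balanced leave-one-out decoder is O(trials × bins) SVM fits per
  session; decoding all 38 bins of a 225-trial session takes tens of
  seconds. The `bins` argument restricts decoding to the analysis bins.
- Exact scale invariance of accuracy holds only in the separable regime:
  with a fixed box constraint, rescaling all inputs changes the effective
  regularization.
- The forward model's planted selectivity is purely amplitude-modulated
  and event-locked; it cannot express latency coding or suppression
  (negative modulation below baseline).
- The perseveration censoring rule bounds unresolved runs below their true
  length; sessions ending mid-run therefore bias the index slightly
  downward, but less than dropping the runs entirely would.
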