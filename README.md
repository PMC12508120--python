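# revdecode

Trial-aligned calcium-trace decoding and behavioral strategy analysis for
probabilistic reversal learning.

## The problem

In a touchscreen reversal-learning task, a rat initiates each trial at a
center stimulus and chooses a left or right stimulus; one side carries the
higher reward probability and the better side reverses every 75 committed
trials (3 blocks, 225 trials per session). Across sessions the
probability ratio becomes more uncertain: 100:0 → 90:10 (schedule 1),
90:10 → 80:20 (schedule 2), 80:20 → 70:30 (schedule 3). Rewarded trials
deliver a pellet 1 s after the choice nosepoke; unrewarded trials incur a
5 s timeout; trials are separated by a 10 s ITI. Miniscope calcium imaging
(20 fps, detrended fluorescence) records frontal-cortex neurons (OFC or M2)
during learning.

`revdecode` implements the full analysis chain for this kind of experiment,
together with a synthetic-data generator (task simulator, parametric
choice agents, and an event-locked fluorescence forward model with planted
selectivity) so every stage is testable without any recording:

- **alignment** — event-aligned windows (4 s around initiation, −1 s to
  +3 s around choice, 1 s around reward-port entry) with overlapping-bin
  downsampling: bin 1 averages frames 1–6, bin 2 frames 3–9, … (width 6,
  stride 2).
- **decoding** — per-bin balanced leave-one-trial-out linear decoding. For
  each held-out trial *t*, draw *m* trials from each of the four
  side × outcome conditions (*m* = the within-session minimum after
  excluding *t*), train a linear-kernel SVM on the bin-*b* population
  vector, and score the held-out trial; accuracy(b) = mean over trials.
  Chance is estimated by circularly shifting the label sequence by a random
  nonzero offset and rerunning; the link to single cells by ablating the
  top-|weight| cells.
- **selectivity** — per-cell linear models on the analysis-bin activity γ:
  γ ~ 1 + side for *Chosen Side*, γ ~ 1 + rewarded + side for *Trial
  Outcome* and *Reward Retrieval* (side as covariate), with a cell called
  selective at p < 0.05 (uncorrected), session-level selective-cell ratios,
  and cross-validated peak-aligned difference heatmaps (odd trials set the
  alignment, even trials are displayed).
- **behavior** — p(Better), Win-Stay, Lose-Shift, Perseveration Index
  (mean trials to change choice after the first unrewarded trial of a loss
  run), Flexibility Index
  `FlexIndex = mean(mean(m1, m2), mean(m2, m3))` over block means of the
  better-choice indicator, latency medians, and moving-window strategy
  traces.
- **stats** — design matrices and GLMs: trial-level binomial models of the
  better-choice indicator (TrialNum, Block, Schedule, Session, Area, Drug,
  Order) and session-level models of pre-event-bin decoding accuracy on
  strategy indices and latencies, with standard codings (0 = OFC / 1 = M2,
  0 = VEH / 1 = CNO, 0 = female / 1 = male).

## Worked example

```python
import numpy as np
import revdecode as rd
from revdecode.task import session_duration
from revdecode.alignment import CHOICE_EPOCH

cfg = rd.TaskConfig(schedule_id=2)                       # 90:10 -> 80:20
agent = rd.AgentParams(kind="wsls", p_stay_after_win=0.85,
                       p_shift_after_loss=0.7)
trials = rd.simulate_session(cfg, agent, seed=11)

beh = rd.summarize_behavior(trials)

cells = rd.CellPopulation.mixed(30, frac_side=0.2, frac_outcome=0.2,
                                modulation_depth=2.0, seed=1)
traces = rd.generate_traces(trials, cells, session_duration(trials, cfg),
                            seed=2)
tensor = rd.bin_downsample(rd.extract_epoch(traces, trials, CHOICE_EPOCH))
labels = rd.make_labels(trials)
pre = rd.pre_event_bin(tensor)
res = rd.loo_decode(tensor, labels, target="side", seed=3,
                    bins=np.array([pre]))
null = rd.shuffle_null(tensor, labels, target="side", n_shuffle=20,
                       seed=3, bins=np.array([pre]))
```

prints (via the obvious `print` statements):

```
p(Better)            0.716
Win-Stay             0.562
Lose-Shift           0.232
Perseveration Index  1.71
Flexibility Index    0.713
median choice latency 1.53 s
pre-choice bin       8 (bin center -0.175 s)
decoding accuracy    1.000
shuffle null         0.495
```

The simulated rat follows the better side 71.6% of the time and adapts
across the two reversals (Flexibility Index 0.71). With 20% planted
side-selective cells (modulation depth 2) the chosen side is decoded
perfectly from the bin just before the choice nosepoke — bin 8, the last
6-frame bin entirely preceding the anchor — while the shuffled-label null
sits at chance.

The same stages are available from the shell:

```sh
revdecode simulate --config config.json --seed 7 --out out/
revdecode traces   --config config.json --trials out/trials.tsv --seed 8 --out out/
revdecode decode   --trials out/trials.tsv --traces out/traces.h5 \
                   --epoch choice --target side --seed 9 --out out/
revdecode behavior --trials out/trials.tsv --out out/
```

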