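# kinedecode

Single-trial decoding of social decisions from reach-to-grasp movement
kinematics in a motor Ultimatum Game.

## The problem

In the motor Ultimatum Game a responder reacts to a monetary offer
(EUR 1–5 out of 10) by reaching for and grasping one of two cylinders
labeled *accept* and *reject* while their arm and hand are motion-captured
at 100 Hz.  The scientific question: does the movement itself carry
single-trial information about the upcoming **choice** (accept vs reject)
and about the perceived **fairness** of the offer (fair: EUR 4–5; unfair:
EUR 1–2), and is that information expressed in responder-specific
kinematic patterns that do not generalize across individuals?

`kinedecode` is a tested, reusable implementation of the full analysis
for researchers in movement science and behavioral neuroscience:

* **kinematics** — marker trajectories → the 170-dimensional single-trial
  kinematic vector *K* (17 variables × 10 time epochs): 6 Hz zero-phase
  Butterworth filtering, 20 mm/s reach segmentation, global (wrist,
  grip-aperture) and hand-local (finger/dorsum plane) variables, epoch
  averaging over normalized movement time, within-responder z-scoring.
* **decoder** — responder- and side-specific elastic-net penalized
  logistic regression P(y=1|K) = σ(β₀ + βᵀK), class-rebalanced, α = 0.95,
  λ tuned by nested leave-one-trial-out CV over logspace(1, −3, 5); the
  full task battery including conditional tasks, generalization to
  held-out mid-range (EUR 3) offers, and a leave-one-subject-out control.
* **nulls** — trial-shuffle and random-guess null distributions of the
  median balanced accuracy, empirical p = r/n_c, and a false-positive-rate
  calibration study on zero-signal cohorts.
* **weights** — median fold weights with 2.5·MAD outlier removal,
  shuffle-based two-tailed significance with Benjamini–Hochberg FDR,
  cross-responder weight correlations, and the feature-concentration
  binomial test.
* **altmodels** — the four comparison classifiers (multi-task LR, static
  weights + evidence integration, encoding–decoding, SE-ARD Gaussian-
  process regression) under the same CV protocol.
* **embedding** — t-SNE maps of trial vectors (perplexity 15).
* **synth** — a generator emulating the full design (12/12/12/16/16
  offers + 12 control trials per session, counterbalanced cylinder sides,
  offer-dependent acceptance curves, additive sparse choice/fairness
  effects, minimum-jerk reach trajectories with grasp-aperture profiles),
  so every stage runs without any data download.

See `docs/methods.md` for the model details, conventions and the
deliberate deviations where the published procedure is silent.

## Worked example

```python
import numpy as np
from kinedecode import synth, decoder, nulls
from kinedecode.kinematics import zscore_within_responder

# a cohort of 5 synthetic responders, 2 sessions each
profiles = synth.make_cohort(5, seed=7, effect_scale=0.8)
trials, X = synth.simulate_dataset(profiles, n_sessions=2, seed=8)
Xz, _ = zscore_within_responder(X, trials["responder"].to_numpy())

# the upper 3 points of the lambda grid keep the 50 shuffle-null decodes
# at a few minutes on one CPU; the default is the full 5-point grid
grid = (10.0, 1.0, 0.1)
task = decoder.task_battery()["choice"]
run = decoder.run_task(trials, Xz, task, side="right", lambda_grid=grid)
for r, cv in run.results.items():
    print(r, round(cv.balanced_accuracy, 3))
print("median:", round(run.median_balanced_accuracy, 3))

null = nulls.trial_shuffle_null(trials, Xz, task, "right",
                                n_shuffles=50, seed=0, lambda_grid=grid)
print("p =", nulls.empirical_p(run.median_balanced_accuracy, null))
```

prints (seeds as above):

```
r00 0.91
r01 0.824
r02 0.637
r03 0.893
r04 0.853
median: 0.853
p = 0.0
```

Each line is one responder's leave-one-trial-out balanced accuracy for
decoding accept vs reject from rightward movements; the median across
responders (0.853) is the cohort summary statistic, and `p = 0.0` means
no trial-shuffle null sample reached it — the planted choice effects are
detected.  The same battery on a zero-signal cohort
(`effect_scale=0.0`) stays at chance with a calibrated test (see below).

The end-to-end pipeline, from a YAML config to CSV tables, plots and a
run summary:

```bash
kinedecode run --out results/demo --seed 7
kinedecode synth --responders 6 --seed 0 --out data/ --raw-markers
kinedecode decode --trials data/trials.csv --features data/features.csv \
    --task choice --side right
```

## Output schemas

* trial table CSV: `responder,session,trial,offer,accept_side,choice,side,is_control,fairness`
* feature CSV: `responder,trial,side,<variable>_<epoch>`... in the fixed
  170-column order of `kinedecode.kinematics.FEATURE_NAMES`
* marker CSV: `time_s,<marker>_x,<marker>_y,<marker>_z` (mm)
* per-task results CSV: `task,side,responder,balanced_accuracy,n_class0,n_class1`

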