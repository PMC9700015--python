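# Methods

## The scientific problem

In a motor version of the one-shot Ultimatum Game, a responder reacts to a
monetary offer (EUR 1-5 out of 10) by reaching out and grasping one of two
cylinders labeled *accept* and *reject*, placed left and right of the body
midline, with the label-to-side assignment swapped between the two
sessions.  The question the analysis answers is whether the reach-to-grasp
movement itself carries single-trial information about (a) the upcoming
choice (accept vs reject) and (b) the perceived fairness of the offer
(fair, EUR 4-5, vs unfair, EUR 1-2), and whether that information is
expressed in responder-specific ("idiosyncratic") kinematic patterns.

`kinedecode` implements the full single-subject, single-trial decoding
pipeline for this design, plus a synthetic-data generator that emulates
the design closely enough that every stage — filtering, segmentation,
feature extraction, penalized decoding, permutation statistics, weight
analysis — runs and is testable end to end without any external data.

## Kinematic features

Marker trajectories (100 Hz motion capture) are low-pass filtered with a
6 Hz second-order Butterworth filter applied forward-backward.  The
zero-phase (forward-backward) application is a deliberate choice: the
filter's phase lag would otherwise bias the timing of threshold-crossing
events; the effective magnitude response is the squared second-order
Butterworth gain.  Filtering is applied to marker positions; wrist speed
is then the magnitude of the central-difference velocity of the radial
wrist marker.

The reach is segmented by a 20 mm/s wrist-speed threshold: onset is the
first sample at or above threshold; offset is the last sample at or above
threshold before the speed stays below threshold for at least 100 ms.
The 100 ms rest criterion makes the offset robust to brief corrective
re-crossings, on which the procedure is otherwise silent.

Seventeen variables are computed on the segment: five global (wrist speed;
the x, y, z wrist position; grip aperture = thumb-tip to index-tip
distance) and twelve local (index-tip and thumb-tip coordinates in a
hand-centered frame; the unit-normal components of the finger plane
spanned by thu3, ind3, ind1 and of the dorsum plane spanned by ind1, lit3,
wrist).  The hand-local frame is constructed with origin at the wrist
marker, primary axis wrist -> ind1, the plane completed with lit3 and
orthonormalized right-handed.  Plane "components" are the components of
the unit normal; the sign is fixed at movement onset (pointing along the
hand frame's dorsal axis) and kept temporally continuous.  These two
conventions are declared package choices: the source procedure states only
"centered on the hand" and does not define a normal sign.

Each variable is resampled by cubic interpolation onto 101 points of
normalized movement time and averaged within each decile, giving 10 epoch
values per variable and a 170-dimensional single-trial vector.  Epoch
*means* (rather than single resampled points) are a declared choice; for a
variable linear in time the epoch values are analytically 0.05, 0.15, ...,
0.95, which the tests assert.

Feature vectors are z-scored per feature within each responder (n-1 SD
convention; zero-variance features are set to 0 and logged).  Z-scoring is
done once per responder on all trials, replicating the published
procedure; a fold-safe variant (training-fold statistics only) can be
assembled from the same primitives for leakage audits.

## The decoder

Choice and fairness are decoded per responder and per movement side with a
weighted elastic-net penalized logistic regression

    P(y=1|K) = sigma(beta0 + beta' K),

fit by minimizing the class-rebalanced negative binomial log-likelihood
plus lambda [ (1-alpha)/2 ||beta||^2 + alpha ||beta||_1 ], with alpha =
0.95.  Trial weights are w_i = n / (2 n_class(i)) — inversely proportional
to class frequency and normalized to mean 1; the normalization interacts
with the lambda scale and is therefore fixed and documented.  The solver
is a glmnet-style IRLS + cyclic coordinate descent with an active-set
strategy, warm starts along the descending lambda path, a monotone
step-halving safeguard for near-separable data, coordinate tolerance 1e-7
and an objective-change stop at 1e-9 relative.  Tests pin the optimum
against an exhaustive grid search and against an independent library
solver.

Lambda is tuned by nested leave-one-trial-out cross-validation over the
grid logspace(1, -3, 5): for each held-out trial, an inner LOTO on the
remaining trials scores each lambda by balanced accuracy; ties resolve
toward the larger lambda (more regularized).  The selection statistic and
tie rule are declared choices.  Inner-fold fits, which contribute only a
binary prediction to the selection, run at a looser tolerance (1e-4); the
per-fold models kept for the weight analysis are fit at full tolerance.

One numerical subtlety is worth recording: under exact class rebalancing a
fully-shrunk model's optimal intercept is exactly 0, and the fitted value
is +/-1e-17 floating-point residue whose sign tracks which class lost a
training trial.  Thresholding P > 0.5 would then "predict" held-out labels
from rounding noise.  The decision rule therefore uses an epsilon above
the 0.5 threshold, so null models yield honest chance-level predictions.

The task battery: choice and fairness on fair + unfair offers (EUR 3
excluded); choice on unfair trials only; fairness on accepted trials only;
generalization of choice classifiers trained on fair/unfair offers to
held-out EUR 3 trials; and a leave-one-subject-out control in which
models trained on all other responders are tested on the left-out one
(lambda tuned by inner leave-one-subject-out, scored by mean balanced
accuracy).  Responders contribute only if every class has at least four
trials; exclusions are logged, not raised.  Optional stratified
subsampling to 50% or 75% of trials supports data-fraction re-analyses.

## Statistics

Performance is summarized as the median across responders of the balanced
accuracy (mean of true-positive and true-negative rates).  Significance
uses two nulls: the trial-shuffle null (labels permuted without
replacement within responder, full nested-CV decode rerun; 100 shuffles by
default) and the cheaper random-guess null (predictions drawn from the
training class distribution; 1000 samples).  Empirical p = r / n_c with r
the count of null samples >= observed; p may be exactly 0, reproducing the
published formula, with an optional (r+1)/(n_c+1) correction flag.

The calibration study regenerates zero-signal cohorts (effect vectors
identically zero), reruns decode + shuffle null, and reports the fraction
of repeats with p below the significance threshold, with an exact
Clopper-Pearson binomial CI.  Validity of the permutation test does not
depend on the lambda grid, so the calibration study runs at a reduced
3-point grid (10, 1, 0.1) and half the trials per responder (the
data-fraction option), which keeps 20 repeats x 50 shuffles of the full
nested CV at desk scale (minutes, one CPU).  These scalings are the
package's declared study conditions for calibration.

Weight analysis: per responder, the coefficient pattern is the
per-coefficient median across LOTO fold models after removing values
outside median +/- 2.5 raw MAD (no 1.4826 scaling; when MAD = 0, any
value different from the median is an outlier; if removal empties a
coefficient the raw median is kept and logged).  Shuffled-label refits
(medians without outlier removal — a deliberately conservative asymmetry)
give per-coefficient two-tailed empirical p-values, 2 min(#>=, #<=)/n_c
capped at 1, tested only where the median coefficient is non-zero, with
Benjamini-Hochberg FDR at alpha = 0.05.  The shuffle refits reuse the
median lambda selected on the real data rather than re-tuning per shuffle;
the published procedure is silent here and re-tuning would multiply cost
by the grid size times the trial count.  Cross-responder similarity is the
Pearson correlation of |median weight| vectors.  The concentration test
treats the M significant weights over n responders as uniformly spread
over the 170 features under the null, so the per-feature count x is
Binomial(n, M/(170 n)), tested one-tailed (upper).

## Alternative classifiers

Four comparison models share the LOTO protocol and balanced accuracy:

* **MTLR** (multi-task logistic regression): joint choice + fairness loss
  under +/-1 label coding with penalty lam1 [(1-alpha) ||B||_F^2 + alpha
  ||B||_{2,1}] and coupling (1-lam2)/lam2 sum_r ||beta_r - mean||^2,
  minimized by L-BFGS.  The 2,1 group norm is smoothed with eps = 1e-12
  so gradient methods apply.  lam2 = 1 removes the coupling; with
  alpha = 0 the fit then matches two independent single-task ridge fits,
  which a test asserts.  Grids: lam1 in logspace(-3, 3, 7), lam2 in
  linspace(0.1, 1, 19).
* **SWLR** (static weights + time integration): a single weight vector
  over the 17 variables, applied per epoch, with cumulative evidence
  p(t) = sigma(beta0 + K(t)'beta + w (p(t-1) - 1/2)), p(0) = 1/2; the
  trial is classified from p at 100% movement time.  The recursion's
  carried term is read as the previous-step cumulative probability — the
  only reading that yields a computable forward pass at test time.
  Training is full-batch Adam (step 1e-2, plateau early-stop) on the
  rebalanced negative log-likelihood of the final probability with an L2
  penalty on beta *and* w (bias unpenalized): leaving the cumulation
  coefficient unpenalized makes the recursion bistable and held-out
  predictions erratic.
* **ED** (encoding-decoding): each feature linearly encoded on choice,
  fairness and their interaction (effects +/-1 coding, a declared choice),
  fit by least squares; decoding inverts the encoding by Bayes' theorem
  under Gaussian noise and conditional independence of features, with
  empirical outcome-cell priors (empty cells dropped and logged).
* **GPR**: Gaussian-process regression on the 0/1 targets with an SE-ARD
  covariance (per-feature length-scales), zero mean (features are
  z-scored), 1e-6 diagonal jitter; hyperparameters minimize the negative
  log marginal likelihood by Polak-Ribiere conjugate gradients (<= 1000
  iterations) over 10 random restarts with log-hyperparameters drawn
  uniformly in [-2, 2] (clipped to [-15, 15] during line search so exp
  cannot overflow).  The predictive mean is thresholded at 1/2; exact
  ties predict at random.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed:

* **Design**: per session, 12/12/12/16/16 offers of EUR 1-5 (68 game
  trials) plus 12 control trials (6 per side), order randomized by seed;
  the accept-cylinder side alternates between sessions.  Because the
  movement side follows from the choice and the session's mapping, each
  side accumulates both accept and reject trials only across the two
  sessions — single-session datasets are single-class per side, exactly as
  in the real design.
* **Behavior**: choices are independent Bernoulli draws from a monotone
  acceptance curve; the default is a logistic in offer value least-squares
  fitted on the logits of the published group means (13.4, 36.3, 64.6,
  96.13, 98.4%).  No trial-history effects are modeled, deliberately.
* **Features**: K = baseline + 1[accept] beta_choice + 1[fair] beta_fair +
  noise, with per-responder baselines N(0, 2^2), sparse effect vectors
  (10% of the 170 features, magnitude 0.8, random signs — mirroring the
  sparse weight maps the decoder recovers), and unit Gaussian trial noise.
  Mid-range offers carry no fairness term.  Effect scale 0 gives
  zero-signal cohorts for calibration.  With these defaults a responder's
  within-responder decoding sits in the high-0.8s/low-0.9s — the regime
  the method is designed for — while independently drawn effect vectors
  make leave-one-subject-out decoding sit at chance.
* **Markers**: minimum-jerk wrist transport to the side-appropriate target
  (44 cm ahead, 18 cm lateral) with a sinusoidal vertical lift, so the
  speed profile is bell-shaped with analytically known 20 mm/s crossings;
  grip aperture opens along a minimum-jerk segment to its 90 mm peak at
  70% of movement time and closes onto the cylinder; rigid hand-marker
  offsets; 0.3 s rest padding; additive 0.3 mm measurement noise.  The
  planted event times and peak aperture are carried in the trajectory
  metadata so segmentation and feature extraction are tested against
  ground truth.

What the generator does *not* emulate: marker dropout and relabeling
noise, hand rotation (marker offsets are rigid and unrotated), movement
duration differences between conditions, trial-history dependence, and
any nonlinear coupling between decision variables and kinematics.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under the additive-Gaussian emulation, not the real-data
effect sizes; published real-data accuracies are responder-specific
quantities that this package does not claim to reproduce.

## Problem sizes

The tests and the acceptance script run the expensive stochastic studies
at deliberately reduced, fixed sizes chosen as the package's study
conditions: calibration uses 5 responders, two sessions at data fraction
0.5 (about 28 trials per responder and side), the 3-point lambda grid, 50
shuffles and 20 repeats; the idiosyncrasy comparison uses the same cohort
shape with the default planted effects; support recovery uses one
responder per seed (68 trials, single side pooled by construction) over
20 seeds with 100-shuffle weight nulls.  Unit tests use toy problems
small enough for exhaustive oracles.

## Known limitations

* The calibration FPR inherits the granularity of p = r/n_c at 50
  shuffles: the smallest nonzero p is 0.02 and P(p < 0.05) under the null
  is 3/51, slightly above 0.05; ties in balanced accuracy push it back
  toward conservative.
* The LOSO control tunes lambda on a per-left-out-responder basis over
  only a handful of training responders; with small synthetic cohorts its
  null band is wide.
* Centroid-like comparison models (ED, GPR) show the known leave-one-out
  pessimism on null data (accuracy below 0.5); their chance bands are the
  permutation nulls of the same estimator, not 0.5.
* The elastic-net path at lambda = 1e-3 on near-separable data is the
  numerically hardest regime; the solver's safeguard plus objective stop
  keeps it stable, at slightly relaxed final precision there.
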