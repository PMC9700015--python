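"""Null distributions and calibration of the significance machinery.

Two nulls are available for the decoding performance statistic (the median
balanced accuracy across responders):

* the trial-shuffle null — the class labels are randomly permuted within
  each responder (destroying any kinematics-label association) and the
  full nested LOTO-CV decoding is rerun; 100 shuffles by default;
* the random-guess null — a classifier that draws predictions from the
  training set's class distribution; 1000 samples by default.

Empirical p-values follow p = r / n_c, where r counts null samples greater
than or equal to the observed statistic; p may be exactly 0 (an optional
(r+1)/(n_c+1) correction is exposed).  The false-positive-rate calibration
study reruns decoding + shuffle null on freshly generated zero-signal
cohorts and reports the fraction of repeats declared significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import decoder, synth
from .decoder import TaskSpec, PreparedResponder
from .kinematics import zscore_within_responder

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Samples of a summary statistic under a stated null."""

    samples: np.ndarray
    statistic_label: str
    seed: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_c(self) -> int:
        return self.samples.size

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))


def empirical_p(
    observed: float, null: NullDistribution, correction: bool = False
) -> float:
    """p = #(null >= observed) / n_c; optionally (r+1)/(n_c+1)."""
    if null.n_c < 1:
        raise ValueError("null distribution is empty")
    r = int(np.sum(null.samples >= observed))
    if correction:
        return (r + 1) / (null.n_c + 1)
    return r / null.n_c


def _decode_prepared(
    prepared: dict[str, PreparedResponder],
    labels: dict[str, np.ndarray],
    lambda_grid,
    alpha,
    tol,
    tol_inner,
) -> float:
    """Median balanced accuracy across responders for given labels."""
    accs = []
    for r, prep in prepared.items():
        cv = decoder.loto_cv_decode(
            prep.X_train, labels[r], lambda_grid, alpha, tol, tol_inner,
            responder_id=r,
        )
        accs.append(cv.balanced_accuracy)
    return float(np.median(accs))


def trial_shuffle_null(
    trials,
    X: np.ndarray,
    task: TaskSpec,
    side: str,
    n_shuffles: int = 100,
    seed: int = 0,
    lambda_grid=decoder.LAMBDA_GRID,
    alpha: float = decoder.ALPHA_DEFAULT,
    min_per_class: int = decoder.MIN_TRIALS_PER_CLASS,
    tol: float = 1e-7,
    tol_inner: float = 1e-4,
    max_retries: int = 3,
) -> NullDistribution:
    """Trial-shuffle null of the median balanced accuracy.

    For each shuffle, labels are permuted without replacement within each
    responder (class counts conserved exactly) and the full nested LOTO-CV
    decode is rerun; the median balanced accuracy across responders is one
    null sample.  A failed shuffle is retried with a fresh permutation
    (logged), up to ``max_retries`` times.
    """
    prepared, _ = decoder.prepare_task(trials, X, task, side, min_per_class, seed)
    if not prepared:
        raise ValueError("no responder passes the inclusion rule")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    samples = np.empty(n_shuffles)
    for s in range(n_shuffles):
        for attempt in range(max_retries):
            labels = {r: rng.permutation(p.y_train) for r, p in prepared.items()}
            try:
                samples[s] = _decode_prepared(
                    prepared, labels, lambda_grid, alpha, tol, tol_inner
                )
                break
            except Exception as exc:  # retried with a new permutation
                logger.warning("shuffle %d attempt %d failed: %s", s, attempt, exc)
        else:
            raise RuntimeError(f"shuffle {s} failed {max_retries} times")
    return NullDistribution(samples, "trial_shuffle_median_balanced_accuracy", seed)


def random_guess_null(
    trials,
    X: np.ndarray,
    task: TaskSpec,
    side: str,
    n_samples: int = 1000,
    seed: int = 0,
    min_per_class: int = decoder.MIN_TRIALS_PER_CLASS,
) -> NullDistribution:
    """Random-guess null: predictions drawn from the class distribution.

    Each null sample draws, per responder, predictions Bernoulli(q) with q
    the training-set frequency of class 1, scores them against the true
    labels, and takes the median balanced accuracy across responders.
    """
    prepared, _ = decoder.prepare_task(trials, X, task, side, min_per_class, seed)
    if not prepared:
        raise ValueError("no responder passes the inclusion rule")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    samples = np.empty(n_samples)
    ys = [p.y_train for p in prepared.values()]
    qs = [y.mean() for y in ys]
    for s in range(n_samples):
        accs = [
            decoder.balanced_accuracy(y, (rng.random(y.size) < q).astype(float))
            for y, q in zip(ys, qs)
        ]
        samples[s] = np.median(accs)
    return NullDistribution(samples, "random_guess_median_balanced_accuracy", seed)


@dataclass
class CalibrationConfig:
    """Study conditions for the false-positive-rate calibration.

    Zero-signal synthetic cohorts (effect vectors identically 0), decoded
    with the standard within-responder pipeline at a reduced lambda grid
    and half the trials per responder (the task's data-fraction option), so
    repeated refits of the nested CV stay tractable.
    """

    n_responders: int = 5
    n_sessions: int = 2
    side: str = "right"
    target: str = "choice"
    data_fraction: float = 0.5
    noise_sd: float = 1.0
    effect_scale: float = 0.0  # 0 = zero-signal (FPR); > 0 turns this into a power check
    lambda_grid: tuple[float, ...] = (10.0, 1.0, 0.1)
    alpha: float = decoder.ALPHA_DEFAULT
    n_shuffles: int = 50
    threshold: float = 0.05
    tol: float = 1e-7
    tol_inner: float = 1e-4


@dataclass
class CalibrationResult:
    fpr: float
    n_repeats: int
    alpha: float
    ci_low: float
    ci_high: float
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))


def fpr_calibration(
    config: CalibrationConfig | None = None,
    n_repeats: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Empirical false-positive rate of the shuffle-null significance test.

    Each repeat generates a fresh zero-effect cohort, runs the LOTO-CV
    decode and its trial-shuffle null, and records whether the empirical p
    falls below ``alpha``.  The rate is reported with an exact (Clopper-
    Pearson) binomial 95% CI.
    """
    if config is None:
        config = CalibrationConfig()
    if n_repeats < 5:
        logger.warning("n_repeats < 5: the binomial CI will be uninformative")
    task = TaskSpec(
        "calibration", config.target, data_fraction=config.data_fraction
    )
    ss = np.random.SeedSequence(seed)
    p_values = np.empty(n_repeats)
    for rep, child in enumerate(ss.spawn(n_repeats)):
        s_cohort, s_data, s_null, s_prep = (int(c.generate_state(1, np.uint64)[0] >> 33) for c in child.spawn(4))
        profiles = synth.make_cohort(
            config.n_responders, s_cohort, effect_scale=config.effect_scale,
            noise_sd=config.noise_sd,
        )
        trials, X = synth.simulate_dataset(profiles, config.n_sessions, s_data)
        Xz, _ = zscore_within_responder(X, trials["responder"].to_numpy())
        run = decoder.run_task(
            trials, Xz, task, config.side, config.lambda_grid, config.alpha,
            seed=s_prep, tol=config.tol, tol_inner=config.tol_inner,
        )
        null = trial_shuffle_null(
            trials, Xz, task, config.side, config.n_shuffles, s_prep,
            config.lambda_grid, config.alpha,
            tol=config.tol, tol_inner=config.tol_inner,
        )
        p_values[rep] = empirical_p(run.median_balanced_accuracy, null)
        logger.info("calibration repeat %d: p = %.3f", rep, p_values[rep])
    hits = int(np.sum(p_values < alpha))
    lo, hi = proportion_confint(hits, n_repeats, alpha=0.05, method="beta")
    return CalibrationResult(
        fpr=hits / n_repeats,
        n_repeats=n_repeats,
        alpha=alpha,
        ci_low=float(lo),
        ci_high=float(hi),
        p_values=p_values,
    )
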