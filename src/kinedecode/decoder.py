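"""Responder-specific penalized logistic decoding of choice and fairness.

The classifier is a weighted elastic-net penalized logistic regression
(mixing parameter alpha = 0.95 by default), fitted per responder and per
movement side.  The regularization strength lambda is tuned by a nested
leave-one-trial-out cross-validation (LOTO-CV): for each held-out trial,
an inner LOTO on the remaining trials scores each lambda on the 5-point
grid logspace(1, -3, 5) by balanced accuracy, ties resolved toward the
stronger regularization, and the refit model predicts the held-out trial.
Performance is summarized as balanced accuracy, the mean of the true
positive and true negative rates.

The task battery covers: choice (accept vs reject) and fairness (fair vs
unfair) classification on fair + unfair offers (mid-range EUR 3 excluded),
choice on unfair trials only, fairness on accepted trials only,
generalization of choice classifiers to held-out mid-range offers, and a
leave-one-subject-out (LOSO) control in which models trained on all other
responders are tested on the left-out one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _cd
from .kinematics import N_FEATURES

logger = logging.getLogger(__name__)

# decision threshold on P(y=1); the epsilon keeps fully-shrunk (null) models
# from 'predicting' held-out labels out of 1e-17 floating-point residue in
# the intercept, whose sign tracks which class lost a training trial
PRED_EPS = 1e-10

LAMBDA_GRID = tuple(np.logspace(1, -3, 5))  # 10, 1, 0.1, 0.01, 0.001
ALPHA_DEFAULT = 0.95
MIN_TRIALS_PER_CLASS = 4

FAIR_OFFERS = (4, 5)
UNFAIR_OFFERS = (1, 2)
MID_OFFER = 3


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ElasticNetLRModel:
    """Fitted penalized logistic model: P(y=1|K) = sigma(beta0 + beta.K)."""

    beta: np.ndarray
    beta0: float
    lam: float
    alpha: float
    trial_weights: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def predict_prob(model: ElasticNetLRModel, K: np.ndarray) -> np.ndarray | float:
    """P(y=1|K) for a single vector or a stack of vectors."""
    K = np.asarray(K, dtype=float)
    if K.shape[-1] != model.beta.shape[0]:
        raise ValueError(
            f"feature dimension {K.shape[-1]} != model dimension {model.beta.shape[0]}"
        )
    eta = model.beta0 + K @ model.beta
    p = sigmoid(eta)
    return float(p) if np.ndim(p) == 0 else p


def class_rebalance_weights(y: np.ndarray) -> np.ndarray:
    """Per-trial weights w_i = n / (2 n_class(i)).

    Inversely proportional to training class frequencies, normalized so the
    mean weight is 1; the total weight mass is then equal across classes.
    """
    y = np.asarray(y, dtype=float)
    n1 = y.sum()
    if n1 == 0 or n1 == y.size:
        raise ValueError("both classes must be present")
    return _cd.class_weights_01(y)


def balanced_accuracy(y_true, y_pred) -> float:
    """(TPR + TNR) / 2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.min() == y_true.max():
        raise ValueError("y_true must contain both classes")
    return float(_cd.balanced_accuracy_01(y_true, y_pred))


def fit_penalized_lr(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = ALPHA_DEFAULT,
    weights: np.ndarray | None = None,
    tol: float = 1e-7,
    max_outer: int = 100,
    warm: ElasticNetLRModel | None = None,
) -> ElasticNetLRModel:
    """Minimize the weighted negative binomial log-likelihood + elastic net.

    ``weights`` defaults to the class-rebalancing weights.  Deterministic
    given inputs (cyclic coordinate descent from a fixed start).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if weights is None:
        weights = class_rebalance_weights(y)
    weights = np.asarray(weights, dtype=float)
    beta = warm.beta.copy() if warm is not None else np.zeros(X.shape[1])
    beta0 = warm.beta0 if warm is not None else 0.0
    beta0, ok = _cd.fit_enet(X, y, weights, lam, alpha, beta, beta0, tol, max_outer)
    if not ok:
        raise ConvergenceError(
            f"coordinate descent did not converge (lam={lam}, alpha={alpha}, "
            f"n={X.shape[0]}, p={X.shape[1]}, tol={tol}, max_outer={max_outer})"
        )
    return ElasticNetLRModel(beta=beta, beta0=beta0, lam=lam, alpha=alpha,
                             trial_weights=weights)


@dataclass
class TaskSpec:
    """One classification task of the battery."""

    name: str
    target: str  # 'choice' | 'fairness'
    trial_filter: str = "all"  # 'all' | 'unfair_only' | 'accepted_only'
    train_offers: tuple[int, ...] = (1, 2, 4, 5)
    test_offers: tuple[int, ...] | None = None  # generalization test set
    mode: str = "within_responder"  # | 'leave_one_subject_out'
    data_fraction: float = 1.0

    def __post_init__(self):
        if self.target not in ("choice", "fairness"):
            raise ValueError("target must be 'choice' or 'fairness'")
        if self.trial_filter not in ("all", "unfair_only", "accepted_only"):
            raise ValueError(f"unknown trial_filter {self.trial_filter!r}")
        if self.test_offers is not None and set(self.test_offers) & set(self.train_offers):
            raise ValueError("train and test offer sets must be disjoint")
        if not 0.0 < self.data_fraction <= 1.0:
            raise ValueError("data_fraction must be in (0, 1]")


def task_battery() -> dict[str, TaskSpec]:
    """The five standard tasks (within-responder mode)."""
    return {
        "choice": TaskSpec("choice", "choice"),
        "fairness": TaskSpec("fairness", "fairness"),
        "choice_unfair": TaskSpec(
            "choice_unfair", "choice", trial_filter="unfair_only",
            train_offers=UNFAIR_OFFERS,
        ),
        "fairness_accepted": TaskSpec(
            "fairness_accepted", "fairness", trial_filter="accepted_only"
        ),
        "generalize_mid": TaskSpec(
            "generalize_mid", "choice", test_offers=(MID_OFFER,)
        ),
    }


@dataclass
class CVResult:
    """Held-out predictions and per-fold models for one responder."""

    responder_id: str
    side: str
    task: str
    y_true: np.ndarray
    y_prob: np.ndarray
    y_pred: np.ndarray
    balanced_accuracy: float
    fold_lambdas: np.ndarray | None = None
    fold_betas: np.ndarray | None = None  # (n_folds, p)
    fold_beta0s: np.ndarray | None = None
    n_per_class: dict[int, int] = field(default_factory=dict)
    lambda_grid: tuple[float, ...] = LAMBDA_GRID


@dataclass
class PreparedResponder:
    """Task-selected, aligned arrays for one responder and side."""

    responder_id: str
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray | None = None  # generalization only
    y_test: np.ndarray | None = None


@dataclass
class TaskRunResult:
    task: TaskSpec
    side: str
    results: dict[str, CVResult]
    excluded: list[tuple[str, str]]

    @property
    def median_balanced_accuracy(self) -> float:
        return float(np.median([r.balanced_accuracy for r in self.results.values()]))


def _labels(frame, target: str) -> np.ndarray:
    if target == "choice":
        return frame["choice"].to_numpy(dtype=float)
    return frame["offer"].isin(FAIR_OFFERS).to_numpy(dtype=float)


def prepare_task(
    trials,
    X: np.ndarray,
    task: TaskSpec,
    side: str,
    min_per_class: int = MIN_TRIALS_PER_CLASS,
    seed: int = 0,
) -> tuple[dict[str, PreparedResponder], list[tuple[str, str]]]:
    """Apply side/offer/choice filters and the inclusion rule.

    Returns per-responder prepared arrays plus an exclusion log
    (responder, reason).  Features must already be standardized.
    """
    X = np.asarray(X, dtype=float)
    mask = (~trials["is_control"].astype(bool)) & (trials["side"] == side)
    if task.trial_filter == "unfair_only":
        mask &= trials["offer"].isin(UNFAIR_OFFERS)
    elif task.trial_filter == "accepted_only":
        mask &= trials["choice"] == 1
    prepared: dict[str, PreparedResponder] = {}
    excluded: list[tuple[str, str]] = []
    ss = np.random.SeedSequence(seed)
    responders = sorted(trials.loc[mask, "responder"].unique())
    seeds = {r: s for r, s in zip(responders, ss.spawn(len(responders)))}
    for r in responders:
        rmask = mask & (trials["responder"] == r)
        train_mask = rmask & trials["offer"].isin(task.train_offers)
        frame = trials[train_mask]
        y = _labels(frame, task.target)
        idx = np.flatnonzero(train_mask.to_numpy())
        if task.data_fraction < 1.0 and idx.size:
            rng = np.random.default_rng(seeds[r])
            keep = []
            for cls in (0.0, 1.0):
                cls_idx = np.flatnonzero(y == cls)
                k = int(round(task.data_fraction * cls_idx.size))
                keep.append(rng.choice(cls_idx, size=k, replace=False))
            keep = np.sort(np.concatenate(keep))
            idx, y = idx[keep], y[keep]
        n1 = int(y.sum())
        n0 = y.size - n1
        if min(n0, n1) < min_per_class:
            excluded.append(
                (r, f"fewer than {min_per_class} trials in a class ({n0}/{n1})")
            )
            continue
        prep = PreparedResponder(r, X[idx], y)
        if task.test_offers is not None:
            test_mask = rmask & trials["offer"].isin(task.test_offers)
            ty = _labels(trials[test_mask], task.target)
            if ty.size == 0 or ty.min() == ty.max():
                excluded.append((r, "test set empty or single-class"))
                continue
            prep.X_test = X[np.flatnonzero(test_mask.to_numpy())]
            prep.y_test = ty
        prepared[r] = prep
    return prepared, excluded


def loto_cv_decode(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid=LAMBDA_GRID,
    alpha: float = ALPHA_DEFAULT,
    tol: float = 1e-7,
    tol_inner: float = 1e-4,
    max_outer: int = 100,
    responder_id: str = "",
    side: str = "",
    task: str = "",
) -> CVResult:
    """Nested LOTO-CV decoding of one responder's trials."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1].copy()
    probs, lam_idx, betas, beta0s = _cd.loto_cv(
        X, y, grid, alpha, tol, max_outer, tol_inner
    )
    preds = (probs > 0.5 + PRED_EPS).astype(float)
    return CVResult(
        responder_id=responder_id,
        side=side,
        task=task,
        y_true=y,
        y_prob=probs,
        y_pred=preds,
        balanced_accuracy=balanced_accuracy(y, preds),
        fold_lambdas=grid[lam_idx],
        fold_betas=betas,
        fold_beta0s=beta0s,
        n_per_class={0: int((y == 0).sum()), 1: int((y == 1).sum())},
        lambda_grid=tuple(grid),
    )


def select_lambda_loto(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid=LAMBDA_GRID,
    alpha: float = ALPHA_DEFAULT,
    tol: float = 1e-7,
    tol_inner: float = 1e-4,
    max_outer: int = 100,
) -> float:
    """Pick lambda by LOTO balanced accuracy on (X, y); ties -> larger lambda."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    w = _cd.class_weights_01(y)
    best_lam, best_acc = grid[0], -1.0
    n = y.size
    for lam in grid:
        preds = np.empty(n)
        warm = None
        full = fit_penalized_lr(X, y, lam, alpha, tol=tol, max_outer=max_outer)
        for t in range(n):
            keep = np.arange(n) != t
            yt = y[keep]
            if yt.min() == yt.max():
                preds[t] = 1.0 - y[t]
                continue
            m = fit_penalized_lr(
                X[keep], yt, lam, alpha, tol=tol_inner, max_outer=max_outer, warm=full
            )
            preds[t] = float(predict_prob(m, X[t]) > 0.5 + PRED_EPS)
        acc = balanced_accuracy(y, preds)
        if acc > best_acc + 1e-12:
            best_acc, best_lam = acc, float(lam)
    return best_lam


def _decode_generalization(
    prep: PreparedResponder, task, side, lambda_grid, alpha, tol, tol_inner
) -> CVResult:
    lam = select_lambda_loto(
        prep.X_train, prep.y_train, lambda_grid, alpha, tol=tol, tol_inner=tol_inner
    )
    model = fit_penalized_lr(prep.X_train, prep.y_train, lam, alpha, tol=tol)
    probs = predict_prob(model, prep.X_test)
    preds = (probs > 0.5 + PRED_EPS).astype(float)
    return CVResult(
        responder_id=prep.responder_id,
        side=side,
        task=task.name,
        y_true=prep.y_test,
        y_prob=probs,
        y_pred=preds,
        balanced_accuracy=balanced_accuracy(prep.y_test, preds),
        fold_lambdas=np.array([lam]),
        fold_betas=model.beta[None, :],
        fold_beta0s=np.array([model.beta0]),
        n_per_class={
            0: int((prep.y_train == 0).sum()),
            1: int((prep.y_train == 1).sum()),
        },
        lambda_grid=tuple(np.sort(np.asarray(lambda_grid))[::-1]),
    )


def run_task(
    trials,
    X: np.ndarray,
    task: TaskSpec,
    side: str,
    lambda_grid=LAMBDA_GRID,
    alpha: float = ALPHA_DEFAULT,
    min_per_class: int = MIN_TRIALS_PER_CLASS,
    seed: int = 0,
    tol: float = 1e-7,
    tol_inner: float = 1e-4,
) -> TaskRunResult:
    """Run one task of the battery for every responder on one side.

    ``trials`` is the tidy trial table, ``X`` the row-aligned standardized
    feature matrix.  Responders failing the minimum-four-trials-per-class
    rule are excluded and logged, not raised.
    """
    if task.mode == "leave_one_subject_out":
        return run_task_loso(
            trials, X, task, side, lambda_grid, alpha, min_per_class, seed, tol,
            tol_inner,
        )
    prepared, excluded = prepare_task(trials, X, task, side, min_per_class, seed)
    for r, reason in excluded:
        logger.info("task %s side %s: excluded %s (%s)", task.name, side, r, reason)
    if not prepared and not excluded:
        raise ValueError(f"task {task.name}: no trials on side {side}")
    results: dict[str, CVResult] = {}
    for r, prep in prepared.items():
        if task.test_offers is not None:
            results[r] = _decode_generalization(
                prep, task, side, lambda_grid, alpha, tol, tol_inner
            )
        else:
            results[r] = loto_cv_decode(
                prep.X_train, prep.y_train, lambda_grid, alpha, tol, tol_inner,
                responder_id=r, side=side, task=task.name,
            )
    return TaskRunResult(task=task, side=side, results=results, excluded=excluded)


def run_task_loso(
    trials,
    X: np.ndarray,
    task: TaskSpec,
    side: str,
    lambda_grid=LAMBDA_GRID,
    alpha: float = ALPHA_DEFAULT,
    min_per_class: int = MIN_TRIALS_PER_CLASS,
    seed: int = 0,
    tol: float = 1e-7,
    tol_inner: float = 1e-4,
) -> TaskRunResult:
    """Leave-one-subject-out control: train on all but one responder.

    Lambda is tuned by an inner leave-one-subject-out grid search on the
    training responders (mean balanced accuracy over inner held-out
    responders; ties -> larger lambda).
    """
    prepared, excluded = prepare_task(trials, X, task, side, min_per_class, seed)
    ids = sorted(prepared)
    if len(ids) < 3:
        raise ValueError("LOSO mode needs at least 3 included responders")
    grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    results: dict[str, CVResult] = {}
    for r in ids:
        train_ids = [q for q in ids if q != r]
        best_lam, best_acc = float(grid[0]), -1.0
        for lam in grid:
            accs = []
            for q in train_ids:
                inner_ids = [s for s in train_ids if s != q]
                Xi = np.vstack([prepared[s].X_train for s in inner_ids])
                yi = np.concatenate([prepared[s].y_train for s in inner_ids])
                m = fit_penalized_lr(Xi, yi, lam, alpha, tol=tol_inner)
                pq = (predict_prob(m, prepared[q].X_train) > 0.5 + PRED_EPS).astype(float)
                accs.append(balanced_accuracy(prepared[q].y_train, pq))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_acc, best_lam = acc, float(lam)
        Xt = np.vstack([prepared[s].X_train for s in train_ids])
        yt = np.concatenate([prepared[s].y_train for s in train_ids])
        model = fit_penalized_lr(Xt, yt, best_lam, alpha, tol=tol)
        probs = predict_prob(model, prepared[r].X_train)
        preds = (probs > 0.5 + PRED_EPS).astype(float)
        results[r] = CVResult(
            responder_id=r,
            side=side,
            task=f"{task.name}_loso",
            y_true=prepared[r].y_train,
            y_prob=probs,
            y_pred=preds,
            balanced_accuracy=balanced_accuracy(prepared[r].y_train, preds),
            fold_lambdas=np.array([best_lam]),
            fold_betas=model.beta[None, :],
            fold_beta0s=np.array([model.beta0]),
            n_per_class={
                0: int((prepared[r].y_train == 0).sum()),
                1: int((prepared[r].y_train == 1).sum()),
            },
            lambda_grid=tuple(grid),
        )
    return TaskRunResult(task=task, side=side, results=results, excluded=excluded)
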