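"""Alternative classifiers for model comparison.

Four models of increasing structural diversity, all evaluated with the
same leave-one-trial-out protocol and balanced accuracy as the primary
penalized logistic decoder:

* MTLR — multi-task logistic regression decoding choice and fairness
  jointly, with an elastic-net penalty (Frobenius + 2,1 group norm) and a
  task-coupling term weighted by (1 - lam2)/lam2 that shrinks the two task
  weight vectors toward their mean; optimized by L-BFGS under +/-1 label
  coding.
* SWLR — static (time-independent) weights with sequential integration of
  evidence across the 10 movement epochs: the cumulative probability
  is carried forward through p(t) = sigma(b0 + K(t).b + w (p(t-1) - 1/2)),
  starting from p(0) = 1/2, and the trial is classified from the final
  (100% movement time) probability; trained by full-batch Adam on the
  L2-penalized negative binomial log-likelihood of the final probability.
* ED — encoding-decoding: each feature is linearly encoded on choice,
  fairness and their interaction (effects coding); decoding inverts the
  encoding by Bayes' theorem under Gaussian noise and conditional
  independence of features given the outcome.
* GPR — Gaussian-process regression on the binary targets with an SE-ARD
  covariance (per-feature length-scales), zero mean (features are
  z-scored), hyperparameters by conjugate-gradient minimization of the
  negative log marginal likelihood with random restarts; the predictive
  mean is thresholded at 1/2 (ties broken at random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .decoder import balanced_accuracy, class_rebalance_weights
from .kinematics import N_EPOCHS, N_VARIABLES

logger = logging.getLogger(__name__)

_EPS_21 = 1e-12  # smoothing of the 2,1 group norm for gradient methods


def to_pm1(y: np.ndarray) -> np.ndarray:
    """{0,1} -> {-1,+1} label coding."""
    y = np.asarray(y, dtype=float)
    return 2.0 * y - 1.0


# ---------------------------------------------------------------- MTLR ----

@dataclass
class MTLRModel:
    beta: np.ndarray  # (2, p): rows = (choice, fairness)
    beta0: np.ndarray  # (2,)
    lam1: float
    lam2: float
    alpha: float

    def __post_init__(self):
        if not 0.0 < self.lam2 <= 1.0:
            raise ValueError("task-coupling parameter lam2 must be in (0, 1]")


def _mtlr_loss_grad(params, X, Y, W, lam1, lam2, alpha):
    """L_MTLR and its gradient; Y, W are (n, 2) with Y in {-1, +1}."""
    n, p = X.shape
    beta = params[: 2 * p].reshape(2, p)
    beta0 = params[2 * p :]
    eta = X @ beta.T + beta0  # (n, 2)
    m = -Y * eta
    # log(1 + exp(m)) stably
    loss_data = np.sum(W * np.logaddexp(0.0, m)) / n
    s = 1.0 / (1.0 + np.exp(-np.clip(m, -500, 500)))  # sigma(m)
    g_eta = W * (-Y) * s / n
    g_beta = g_eta.T @ X  # (2, p)
    g_beta0 = g_eta.sum(axis=0)

    frob = np.sum(beta**2)
    group = np.sqrt(np.sum(beta**2, axis=0) + _EPS_21)  # (p,)
    loss_pen = lam1 * ((1.0 - alpha) * frob + alpha * group.sum())
    g_beta += lam1 * (2.0 * (1.0 - alpha) * beta + alpha * beta / group)

    c = (1.0 - lam2) / lam2
    bbar = beta.mean(axis=0)
    dev = beta - bbar
    loss_couple = c * np.sum(dev**2)
    g_beta += 2.0 * c * dev

    loss = loss_data + loss_pen + loss_couple
    return loss, np.concatenate([g_beta.ravel(), g_beta0])


def mtlr_objective(model: MTLRModel, X, y_choice, y_fairness, weights=None) -> float:
    Y = np.column_stack([to_pm1(y_choice), to_pm1(y_fairness)])
    W = _mtlr_weights(y_choice, y_fairness) if weights is None else weights
    params = np.concatenate([model.beta.ravel(), model.beta0])
    loss, _ = _mtlr_loss_grad(params, X, Y, W, model.lam1, model.lam2, model.alpha)
    return float(loss)


def _mtlr_weights(y_choice, y_fairness) -> np.ndarray:
    return np.column_stack(
        [class_rebalance_weights(y_choice), class_rebalance_weights(y_fairness)]
    )


def fit_mtlr(
    X: np.ndarray,
    y_choice: np.ndarray,
    y_fairness: np.ndarray,
    lam1: float,
    lam2: float,
    alpha: float = 0.95,
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> MTLRModel:
    """Joint choice + fairness fit at fixed (lam1, lam2) via L-BFGS."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Y = np.column_stack([to_pm1(y_choice), to_pm1(y_fairness)])
    W = _mtlr_weights(y_choice, y_fairness) if weights is None else weights
    res = optimize.minimize(
        _mtlr_loss_grad,
        np.zeros(2 * p + 2),
        args=(X, Y, W, lam1, lam2, alpha),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"MTLR optimization failed: {res.message}")
    beta = res.x[: 2 * p].reshape(2, p)
    return MTLRModel(beta=beta, beta0=res.x[2 * p :], lam1=lam1, lam2=lam2, alpha=alpha)


def mtlr_predict_prob(model: MTLRModel, X: np.ndarray) -> np.ndarray:
    """(n, 2) probabilities of (accept, fair)."""
    eta = np.asarray(X, dtype=float) @ model.beta.T + model.beta0
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


MTLR_LAM1_GRID = tuple(np.logspace(-3, 3, 7))
MTLR_LAM2_GRID = tuple(np.linspace(0.1, 1.0, 19))


def tune_mtlr(
    X,
    y_choice,
    y_fairness,
    lam1_grid=MTLR_LAM1_GRID,
    lam2_grid=MTLR_LAM2_GRID,
    alpha: float = 0.95,
) -> tuple[float, float]:
    """(lam1, lam2) by nested LOTO-CV, scored by the mean of the two tasks'
    balanced accuracies; ties -> stronger regularization (larger lam1,
    smaller lam2)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = (float(lam1_grid[0]), float(lam2_grid[0]))
    best_acc = -1.0
    for lam1 in sorted(lam1_grid, reverse=True):
        for lam2 in sorted(lam2_grid):
            pc = np.empty(n)
            pf = np.empty(n)
            ok = True
            for t in range(n):
                keep = np.arange(n) != t
                yc, yf = y_choice[keep], y_fairness[keep]
                if yc.min() == yc.max() or yf.min() == yf.max():
                    ok = False
                    break
                m = fit_mtlr(X[keep], yc, yf, lam1, lam2, alpha)
                pr = mtlr_predict_prob(m, X[t : t + 1])[0]
                pc[t], pf[t] = (pr > 0.5).astype(float)
            if not ok:
                continue
            acc = 0.5 * (
                balanced_accuracy(y_choice, pc) + balanced_accuracy(y_fairness, pf)
            )
            if acc > best_acc + 1e-12:
                best_acc, best = acc, (float(lam1), float(lam2))
    return best


# ---------------------------------------------------------------- SWLR ----

@dataclass
class SWLRModel:
    beta: np.ndarray  # (n_variables,) static weights
    beta0: float
    w: float  # evidence-cumulation coefficient
    lam: float


def epochs_view(X: np.ndarray) -> np.ndarray:
    """(n, 170) variable-major features -> (n, 10, 17) per-epoch vectors."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != N_VARIABLES * N_EPOCHS:
        raise ValueError("expected the canonical 170-column feature layout")
    return X.reshape(X.shape[0], N_VARIABLES, N_EPOCHS).transpose(0, 2, 1)


def swlr_forward(model: SWLRModel, X_epochs: np.ndarray) -> np.ndarray:
    """Cumulative probabilities (n, T+1); column 0 is the 1/2 prior."""
    X_epochs = np.asarray(X_epochs, dtype=float)
    if X_epochs.ndim != 3 or X_epochs.shape[2] != model.beta.size:
        raise ValueError("X_epochs must be (n, T, n_variables) in epoch order")
    n, T, _ = X_epochs.shape
    P = np.empty((n, T + 1))
    P[:, 0] = 0.5
    for t in range(T):
        eta = model.beta0 + X_epochs[:, t, :] @ model.beta + model.w * (P[:, t] - 0.5)
        P[:, t + 1] = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    return P


def swlr_fit_predict(
    X_epochs: np.ndarray,
    y: np.ndarray,
    lam: float,
    lr: float = 1e-2,
    max_epochs: int = 3000,
    seed: int = 0,
    X_test: np.ndarray | None = None,
):
    """Train by Adam on the final-epoch loss; returns (model, P_train[, P_test]).

    The loss is the class-rebalanced negative binomial log-likelihood of
    the cumulative probability at 100% movement time plus an L2 penalty
    lam * (||beta||^2 + w^2) on the weights and the cumulation
    coefficient (bias unpenalized; an unpenalized w makes the recursion
    bistable and held-out predictions erratic).  Gradients are
    backpropagated through the T-step recursion.  Training stops early on
    a loss plateau.
    """
    X_epochs = np.asarray(X_epochs, dtype=float)
    y = np.asarray(y, dtype=float)
    n, T, d = X_epochs.shape
    wts = class_rebalance_weights(y)
    rng = np.random.default_rng(seed)
    beta = rng.normal(0.0, 1e-3, d)
    beta0 = 0.0
    wcum = 0.0
    params = np.concatenate([beta, [beta0, wcum]])
    m = np.zeros_like(params)
    v = np.zeros_like(params)
    b1, b2, eps = 0.9, 0.999, 1e-8
    prev_loss = np.inf
    stall = 0
    for epoch in range(1, max_epochs + 1):
        beta, beta0, wcum = params[:d], params[d], params[d + 1]
        P = np.empty((n, T + 1))
        P[:, 0] = 0.5
        etas = np.empty((n, T))
        for t in range(T):
            etas[:, t] = beta0 + X_epochs[:, t, :] @ beta + wcum * (P[:, t] - 0.5)
            P[:, t + 1] = 1.0 / (1.0 + np.exp(-np.clip(etas[:, t], -500, 500)))
        pT = np.clip(P[:, T], 1e-12, 1 - 1e-12)
        loss = -np.mean(wts * (y * np.log(pT) + (1 - y) * np.log(1 - pT)))
        loss += lam * (np.sum(beta**2) + wcum**2)
        # backward pass through the recursion
        dP = -wts * (y / pT - (1 - y) / (1 - pT)) / n  # dL/dP_T
        g_beta = 2.0 * lam * beta
        g_beta0 = 0.0
        g_w = 2.0 * lam * wcum
        for t in range(T - 1, -1, -1):
            deta = dP * P[:, t + 1] * (1.0 - P[:, t + 1])
            g_beta += X_epochs[:, t, :].T @ deta
            g_beta0 += deta.sum()
            g_w += deta @ (P[:, t] - 0.5)
            dP = deta * wcum
        grad = np.concatenate([g_beta, [g_beta0, g_w]])
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        mh = m / (1 - b1**epoch)
        vh = v / (1 - b2**epoch)
        params = params - lr * mh / (np.sqrt(vh) + eps)
        if abs(prev_loss - loss) < 1e-9 * (1.0 + abs(loss)):
            stall += 1
            if stall >= 20:
                break
        else:
            stall = 0
        prev_loss = loss
    model = SWLRModel(beta=params[:d], beta0=float(params[d]), w=float(params[d + 1]), lam=lam)
    P_train = swlr_forward(model, X_epochs)
    if X_test is not None:
        return model, P_train, swlr_forward(model, np.asarray(X_test, dtype=float))
    return model, P_train


SWLR_LAMBDA_GRID = tuple(np.logspace(1, -3, 5))


# ------------------------------------------------------------------ ED ----

@dataclass
class EDModel:
    """Per-feature linear encoding on (choice, fairness, interaction)."""

    coef: np.ndarray  # (4, p): rows = intercept, choice, fairness, interaction
    sigma2: np.ndarray  # (p,)
    cells: list[tuple[int, int]]  # (choice, fairness) in {-1, +1}^2
    priors: np.ndarray  # (n_cells,)


def _ed_design(c_pm1: np.ndarray, f_pm1: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(c_pm1), c_pm1, f_pm1, c_pm1 * f_pm1]
    )


def fit_ed(X: np.ndarray, y_choice: np.ndarray, y_fairness: np.ndarray) -> EDModel:
    """Least-squares encoding fit + empirical outcome priors."""
    X = np.asarray(X, dtype=float)
    c = to_pm1(y_choice)
    f = to_pm1(y_fairness)
    A = _ed_design(c, f)
    coef, *_ = np.linalg.lstsq(A, X, rcond=None)
    resid = X - A @ coef
    dof = max(1, X.shape[0] - A.shape[1])
    sigma2 = np.maximum(np.sum(resid**2, axis=0) / dof, 1e-10)
    cells = []
    priors = []
    for cc in (-1, 1):
        for ff in (-1, 1):
            cnt = int(np.sum((c == cc) & (f == ff)))
            if cnt > 0:
                cells.append((cc, ff))
                priors.append(cnt / X.shape[0])
            else:
                logger.info("ED: empty outcome cell (choice=%d, fair=%d) dropped", cc, ff)
    return EDModel(coef=coef, sigma2=sigma2, cells=cells, priors=np.asarray(priors))


def ed_posteriors(model: EDModel, X: np.ndarray) -> np.ndarray:
    """(n, n_cells) posterior over outcome cells, rows summing to 1."""
    X = np.asarray(X, dtype=float)
    logp = np.empty((X.shape[0], len(model.cells)))
    for k, (cc, ff) in enumerate(model.cells):
        mu = _ed_design(np.array([cc], float), np.array([ff], float)) @ model.coef
        ll = -0.5 * np.sum((X - mu) ** 2 / model.sigma2, axis=1)
        logp[:, k] = ll + np.log(model.priors[k])
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return post


def ed_fit_predict(
    X_train, y_choice, y_fairness, X_test, target: str = "choice"
) -> tuple[EDModel, np.ndarray, np.ndarray]:
    """Fit + marginal-posterior classification of ``target`` on X_test.

    Returns (model, posteriors over cells, binary predictions).
    """
    model = fit_ed(X_train, y_choice, y_fairness)
    post = ed_posteriors(model, X_test)
    axis = 0 if target == "choice" else 1
    p_pos = np.array(
        [post[:, k] for k, cell in enumerate(model.cells) if cell[axis] == 1]
    ).sum(axis=0)
    return model, post, (p_pos > 0.5).astype(float)


# ----------------------------------------------------------------- GPR ----

@dataclass
class GPRModel:
    """SE-ARD Gaussian-process regression on binary targets."""

    log_sf2: float
    log_ls: np.ndarray  # (p,) log length-scales
    log_sn2: float
    X_train: np.ndarray
    y_train: np.ndarray
    nlml: float
    jitter: float = 1e-6


def _se_ard(X1, X2, sf2, ls):
    d = (X1[:, None, :] - X2[None, :, :]) / ls
    return sf2 * np.exp(-0.5 * np.sum(d * d, axis=2))


def gpr_nlml(theta: np.ndarray, X: np.ndarray, y: np.ndarray, jitter: float = 1e-6):
    """Negative log marginal likelihood and gradient wrt log-hyperparameters.

    theta = (log sf2, log l_1..log l_p, log sn2).  Log-hyperparameters
    are clipped to [-15, 15] so line searches cannot overflow exp.
    """
    n, p = X.shape
    theta = np.clip(theta, -15.0, 15.0)
    sf2 = np.exp(theta[0])
    ls = np.exp(theta[1 : 1 + p])
    sn2 = np.exp(theta[1 + p])
    K = _se_ard(X, X, sf2, ls)
    Cy = K + (sn2 + jitter) * np.eye(n)
    try:
        L = np.linalg.cholesky(Cy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (sf2={sf2:.3g}, sn2={sn2:.3g})"
        ) from exc
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    nlml = (
        0.5 * y @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)
    )
    Kinv = np.linalg.solve(L.T, np.linalg.solve(L, np.eye(n)))
    W = np.outer(alpha, alpha) - Kinv  # dNLML/dK = -0.5 W
    grad = np.empty_like(theta)
    grad[0] = -0.5 * np.sum(W * K)  # d/dlog sf2
    for d in range(p):
        D2 = (X[:, d, None] - X[None, :, d]) ** 2 / ls[d] ** 2
        grad[1 + d] = -0.5 * np.sum(W * (K * D2))
    grad[1 + p] = -0.5 * sn2 * np.trace(W)
    return float(nlml), grad


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    jitter: float = 1e-6,
) -> GPRModel:
    """Hyperparameters by Polak-Ribiere CG over random restarts.

    Restart log-hyperparameters are drawn uniformly in [-2, 2]; the
    restart with the smallest final NLML wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        theta0 = rng.uniform(-2.0, 2.0, p + 2)
        try:
            res = optimize.minimize(
                gpr_nlml, theta0, args=(X, y, jitter), method="CG", jac=True,
                options={"maxiter": max_iter},
            )
        except np.linalg.LinAlgError:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise np.linalg.LinAlgError("all GPR restarts failed (non-PD covariance)")
    theta = best.x
    return GPRModel(
        log_sf2=float(theta[0]),
        log_ls=theta[1 : 1 + p].copy(),
        log_sn2=float(theta[1 + p]),
        X_train=X,
        y_train=y,
        nlml=float(best.fun),
        jitter=jitter,
    )


def gpr_predict_mean(model: GPRModel, X_test: np.ndarray) -> np.ndarray:
    X_test = np.asarray(X_test, dtype=float)
    sf2 = np.exp(model.log_sf2)
    ls = np.exp(model.log_ls)
    sn2 = np.exp(model.log_sn2)
    K = _se_ard(model.X_train, model.X_train, sf2, ls)
    Cy = K + (sn2 + model.jitter) * np.eye(K.shape[0])
    Ks = _se_ard(X_test, model.X_train, sf2, ls)
    return Ks @ np.linalg.solve(Cy, model.y_train)


def gpr_fit_predict(
    X_train,
    y_train,
    X_test,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
) -> tuple[GPRModel, np.ndarray]:
    """Fit, then threshold the predictive mean at 1/2 (ties random)."""
    model = fit_gpr(X_train, y_train, n_restarts=n_restarts, seed=seed, max_iter=max_iter)
    mean = gpr_predict_mean(model, X_test)
    rng = np.random.default_rng(seed + 1)
    preds = np.where(mean > 0.5, 1.0, 0.0)
    ties = mean == 0.5
    if ties.any():
        preds[ties] = rng.integers(0, 2, ties.sum()).astype(float)
    return model, preds


# ------------------------------------------------- shared CV evaluation ----

def loto_cv_evaluate(X: np.ndarray, y: np.ndarray, fit_predict) -> float:
    """Leave-one-trial-out balanced accuracy for any fit/predict callable.

    ``fit_predict(X_train, y_train, X_test) -> binary predictions``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    preds = np.empty(n)
    for t in range(n):
        keep = np.arange(n) != t
        yt = y[keep]
        if yt.min() == yt.max():
            preds[t] = 1.0 - y[t]
            continue
        preds[t] = float(np.asarray(fit_predict(X[keep], yt, X[t : t + 1])).ravel()[0])
    return balanced_accuracy(y, preds)
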