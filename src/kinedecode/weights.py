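"""Aggregation and statistics of classifier weight patterns.

A LOTO-CV decode yields one model per held-out trial.  The responder's
weight pattern is the per-coefficient median across fold models after
removing outliers beyond the median +/- 2.5 raw MAD (median absolute
deviation, unscaled).  Significance of individual weights is assessed
against shuffled-label refits (medians taken without outlier removal — a
deliberately conservative asymmetry), with two-tailed empirical p-values
and Benjamini-Hochberg FDR across the non-zero coefficients.

Cross-responder similarity is the Pearson correlation of the absolute
median weight vectors.  The concentration test asks, per feature, whether
more responders carry a significant weight on that feature than expected
if the M significant weights were spread uniformly over the 170-feature
space (one-tailed binomial with p = M / (170 n)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _cd
from .decoder import ALPHA_DEFAULT, CVResult, class_rebalance_weights
from .kinematics import N_FEATURES

logger = logging.getLogger(__name__)

MAD_FACTOR = 2.5


@dataclass
class WeightSummary:
    responder_id: str
    side: str
    task: str
    median_beta: np.ndarray
    p_values: np.ndarray | None = None  # NaN where untested (zero median)
    significant: np.ndarray | None = None
    signs: np.ndarray | None = None
    n_outliers_removed: int = 0


@dataclass
class ConcentrationResult:
    x: np.ndarray  # per-feature count of responders with significant weight
    n: int  # responders tested
    M: int  # total significant weights over all responders
    p_binom: np.ndarray

    @property
    def p_null(self) -> float:
        return self.M / (N_FEATURES * self.n) if self.n else 0.0


def aggregate_weights(
    fold_betas: np.ndarray,
    responder_id: str = "",
    side: str = "",
    task: str = "",
    mad_factor: float = MAD_FACTOR,
) -> WeightSummary:
    """Median fold weights after MAD-based outlier removal, per coefficient.

    Values outside median +/- ``mad_factor`` * MAD across fold models are
    removed before taking the median of the survivors.  The MAD is the raw
    median absolute deviation (no 1.4826 normal-consistency scaling); when
    MAD = 0, any value different from the median counts as an outlier.  If
    removal empties a coefficient, the raw median is used (logged).
    """
    B = np.asarray(fold_betas, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 fold models")
    med = np.median(B, axis=0)
    mad = np.median(np.abs(B - med), axis=0)
    keep = np.abs(B - med) <= mad_factor * mad
    n_removed = int((~keep).sum())
    out = np.empty(B.shape[1])
    for j in range(B.shape[1]):
        vals = B[keep[:, j], j]
        if vals.size == 0:
            logger.info(
                "coefficient %d: all folds removed as outliers; raw median kept", j
            )
            out[j] = med[j]
        else:
            out[j] = np.median(vals)
    return WeightSummary(
        responder_id=responder_id, side=side, task=task,
        median_beta=out, n_outliers_removed=n_removed,
    )


def shuffle_median_weights(
    X: np.ndarray,
    y: np.ndarray,
    fold_lambdas: np.ndarray,
    n_shuffles: int = 100,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
    tol: float = 1e-5,
    max_outer: int = 100,
) -> np.ndarray:
    """Null weight medians from LOTO refits on shuffled labels.

    For each shuffle: labels permuted without replacement, one model per
    left-out trial is refit, and the per-coefficient median across folds is
    taken WITHOUT outlier removal.  The per-fold regularization strength is
    the median lambda selected on the real data (held fixed across
    shuffles).  Returns (n_shuffles, p).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    lam = float(np.median(np.asarray(fold_lambdas, dtype=float)))
    out = np.empty((n_shuffles, p))
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        betas = np.empty((n, p))
        # warm start: fit on all shuffled trials once
        bfull = np.zeros(p)
        wfull = class_rebalance_weights(ys)
        b0full, _ = _cd.fit_enet(X, ys, wfull, lam, alpha, bfull, 0.0, tol, max_outer)
        for t in range(n):
            keep = np.arange(n) != t
            yt = ys[keep]
            if yt.min() == yt.max():
                betas[t] = bfull
                continue
            bt = bfull.copy()
            wt = _cd.class_weights_01(yt)
            _cd.fit_enet(
                np.ascontiguousarray(X[keep]), yt, wt, lam, alpha, bt, b0full,
                tol, max_outer,
            )
            betas[t] = bt
        out[s] = np.median(betas, axis=0)
    return out


def weight_significance(
    summary: WeightSummary,
    null_medians: np.ndarray,
    alpha: float = 0.05,
) -> WeightSummary:
    """Two-tailed empirical p per non-zero coefficient, BH-FDR corrected.

    p = 2 * min(#(null >= obs), #(null <= obs)) / n_c, capped at 1.
    Coefficients with median exactly 0 are excluded from testing.
    """
    null_medians = np.asarray(null_medians, dtype=float)
    if null_medians.ndim != 2 or null_medians.shape[1] != summary.median_beta.size:
        raise ValueError("null medians must be (n_shuffles, p)")
    obs = summary.median_beta
    n_c = null_medians.shape[0]
    nonzero = obs != 0.0
    p = np.full(obs.size, np.nan)
    ge = (null_medians >= obs).sum(axis=0)
    le = (null_medians <= obs).sum(axis=0)
    p[nonzero] = np.minimum(1.0, 2.0 * np.minimum(ge, le)[nonzero] / n_c)
    significant = np.zeros(obs.size, dtype=bool)
    if nonzero.any():
        rejected, _, _, _ = multipletests(
            p[nonzero], alpha=alpha, method="fdr_bh"
        )[:4]
        significant[np.flatnonzero(nonzero)] = rejected
    summary.p_values = p
    summary.significant = significant
    summary.signs = np.sign(obs) * significant
    return summary


def weight_similarity_matrix(summaries: list[WeightSummary]) -> np.ndarray:
    """Pearson correlation of |median weights| between responder pairs.

    Symmetric, diagonal 1; undefined correlations (a zero-variance weight
    vector) are recorded as NaN.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 responders")
    A = np.vstack([np.abs(s.median_beta) for s in summaries])
    n = A.shape[0]
    C = np.eye(n)
    sds = A.std(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if sds[i] == 0 or sds[j] == 0:
                C[i, j] = C[j, i] = np.nan
            else:
                C[i, j] = C[j, i] = np.corrcoef(A[i], A[j])[0, 1]
    return C


def concentration_test(flags: np.ndarray) -> ConcentrationResult:
    """One-tailed binomial test of feature-use concentration.

    ``flags`` is (n_responders, n_features) boolean.  Per feature, x is the
    number of responders with a significant weight; under the null the M
    significant weights are spread uniformly, so x ~ Binomial(n, M/(170 n))
    and the upper-tail probability P(X >= x) is reported.
    """
    flags = np.asarray(flags, dtype=bool)
    n, p_feat = flags.shape
    x = flags.sum(axis=0)
    M = int(flags.sum())
    if M == 0:
        return ConcentrationResult(x=x, n=n, M=0, p_binom=np.ones(p_feat))
    p0 = M / (p_feat * n)
    p_binom = stats.binom.sf(x - 1, n, p0)
    return ConcentrationResult(x=x, n=n, M=M, p_binom=p_binom)


def plot_weight_map(summary: WeightSummary, path=None):
    """17 x 10 heatmap of the median weights (variables x epochs).

    Significant cells (if flags are present) are marked with a dot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinematics import N_EPOCHS, N_VARIABLES, VARIABLE_NAMES

    grid = summary.median_beta.reshape(N_VARIABLES, N_EPOCHS)
    vmax = np.abs(grid).max() or 1.0
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(grid, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    if summary.significant is not None:
        sig = summary.significant.reshape(N_VARIABLES, N_EPOCHS)
        ys, xs = np.nonzero(sig)
        ax.scatter(xs, ys, s=10, c="k", marker=".")
    ax.set_yticks(range(N_VARIABLES), VARIABLE_NAMES, fontsize=6)
    ax.set_xticks(range(N_EPOCHS), [f"{(e + 1) * 10}%" for e in range(N_EPOCHS)],
                  fontsize=6, rotation=45)
    ax.set_xlabel("movement time")
    ax.set_title(f"{summary.responder_id} {summary.task} ({summary.side})")
    fig.colorbar(im, ax=ax, label="median weight")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
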