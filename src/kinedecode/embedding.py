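"""2-D visualization of single-trial kinematic vectors.

t-distributed stochastic neighbor embedding (perplexity 15 by default) of
the 170-dimensional trial vectors, with plotting keys for responder,
choice and fairness.  The embedding is exploratory: proximity in the map
reflects similarity in kinematic space, and no quantitative claim is
attached to the layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n_trials, 2)
    perplexity: float
    seed: int
    params: dict = field(default_factory=dict)
    keys: dict = field(default_factory=dict)  # responder/choice/fairness per trial


def embed_2d(
    X: np.ndarray,
    perplexity: float = 15.0,
    seed: int = 0,
    keys: dict | None = None,
    **tsne_kwargs,
) -> EmbeddingResult:
    """t-SNE of the trial feature vectors (Euclidean metric).

    Requires at least 3 * perplexity trials.  Deterministic under a fixed
    seed.  Implementation defaults for early exaggeration / learning rate
    are kept and recorded in the result metadata.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} trials for perplexity {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        **tsne_kwargs,
    )
    coords = tsne.fit_transform(X)
    params = {
        "metric": "euclidean",
        "init": "pca",
        "learning_rate": tsne.learning_rate,
        "early_exaggeration": tsne.early_exaggeration,
    }
    return EmbeddingResult(
        coords=coords,
        perplexity=perplexity,
        seed=seed,
        params=params,
        keys=dict(keys or {}),
    )


def plot_embedding(result: EmbeddingResult, key: str, path=None):
    """Scatter of the embedding color-coded by one key; optionally saved."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(result.keys[key])
    fig, ax = plt.subplots(figsize=(5, 5))
    for val in np.unique(labels.astype(str)):
        mask = labels.astype(str) == val
        ax.scatter(result.coords[mask, 0], result.coords[mask, 1], s=8, label=str(val))
    ax.set_title(f"t-SNE (perplexity {result.perplexity}) by {key}")
    if len(np.unique(labels.astype(str))) <= 12:
        ax.legend(fontsize=6, markerscale=0.7)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
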