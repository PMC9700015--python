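"""End-to-end orchestration: synthesis, decoding, nulls, weights, report.

A run is described by a :class:`RunConfig` (loadable from YAML).  The full
analysis sequences: synthetic-data generation (or CSV loading) ->
within-responder z-scoring -> the decoding task battery per side ->
trial-shuffle and random-guess nulls with empirical p-values -> weight
aggregation/significance/similarity/concentration -> t-SNE embedding ->
behavioral acceptance rates.  Every stage writes a CSV under the output
directory and the machine-readable summary records seeds and versions, so
each number is traceable to a stage output and a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, decoder, embedding, io, nulls, synth, weights
from .kinematics import FEATURE_NAMES, zscore_within_responder

logger = logging.getLogger(__name__)


def acceptance_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-offer acceptance rate: mean +/- SEM across responders.

    The rate per responder and offer level is accepted/proposed.
    Responders with zero proposals at an offer are excluded from that
    offer's mean (logged).  Returns a frame indexed by offer with columns
    mean, sem, n_responders.
    """
    ug = trials[~trials["is_control"].astype(bool)].copy()
    if ug.empty:
        raise ValueError("no non-control trials")
    rows = []
    for offer, block in ug.groupby("offer"):
        per_resp = block.groupby("responder")["choice"].agg(["mean", "count"])
        missing = set(ug["responder"].unique()) - set(per_resp.index)
        for r in missing:
            logger.info("offer %s: responder %s has no proposals, excluded", offer, r)
        rates = per_resp["mean"].to_numpy(dtype=float)
        sem = rates.std(ddof=1) / np.sqrt(rates.size) if rates.size > 1 else 0.0
        rows.append(
            {"offer": int(offer), "mean": float(rates.mean()), "sem": float(sem),
             "n_responders": int(rates.size)}
        )
    return pd.DataFrame(rows).set_index("offer")


@dataclass
class RunConfig:
    """Declarative description of one full analysis run.

    Defaults mirror the standard analysis constants: 20 mm/s movement
    threshold and 6 Hz filtering (kinematics stage), alpha = 0.95 and the
    5-point lambda grid logspace(1, -3, 5) (decoder), 100 shuffle / 1000
    random-guess null samples at significance threshold 0.05, the
    minimum-4-trials-per-class inclusion rule, 2.5 * MAD outlier removal
    and FDR alpha = 0.05 (weights), t-SNE perplexity 15 (embedding).
    """

    out_dir: str = "kinedecode_run"
    seed: int = 0
    # data source: synthetic cohort ...
    n_responders: int = 6
    n_sessions: int = 2
    effect_scale: float = 0.8
    noise_sd: float = 1.0
    sparsity: float = 0.1
    # ... or pre-existing CSVs (override synthesis when both given)
    trials_csv: str | None = None
    features_csv: str | None = None
    # analysis
    tasks: tuple[str, ...] = ("choice", "fairness")
    sides: tuple[str, ...] = ("right", "left")
    lambda_grid: tuple[float, ...] = decoder.LAMBDA_GRID
    alpha: float = decoder.ALPHA_DEFAULT
    data_fraction: float = 1.0
    min_per_class: int = decoder.MIN_TRIALS_PER_CLASS
    n_shuffles: int = 100
    n_guesses: int = 1000
    significance_alpha: float = 0.05
    fdr_alpha: float = 0.05
    perplexity: float = 15.0
    run_weights: bool = True
    run_embedding: bool = True

    def __post_init__(self):
        if not 0.0 < self.significance_alpha < 1.0:
            raise ValueError("significance threshold must be in (0, 1)")
        for name in ("trials_csv", "features_csv"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("tasks", "sides", "lambda_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_or_synthesize(config: RunConfig):
    if config.trials_csv and config.features_csv:
        trials = io.read_trials(config.trials_csv)
        _, X = io.read_features(config.features_csv)
        profiles = None
    else:
        ss = np.random.SeedSequence(config.seed)
        s_cohort, s_data = ss.spawn(2)
        profiles = synth.make_cohort(
            config.n_responders, int(s_cohort.generate_state(1, np.uint64)[0] >> 33),
            effect_scale=config.effect_scale, noise_sd=config.noise_sd,
            sparsity=config.sparsity,
        )
        trials, X = synth.simulate_dataset(profiles, config.n_sessions, s_data)
    return trials, X, profiles


def run_full_analysis(config: RunConfig) -> dict:
    """Run every requested stage; returns the summary dict (also written).

    Stage failures abort with stage-scoped diagnostics; outputs written by
    earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "exclusions": [],
    }
    stage = "load"
    try:
        trials, X, _ = _load_or_synthesize(config)
        io.write_trials(trials, out / "trials.csv")
        io.write_features(trials, X, out / "features.csv")

        stage = "behavior"
        rates = acceptance_rates(trials)
        rates.to_csv(out / "acceptance_rates.csv")
        summary["stages"]["behavior"] = {
            "acceptance_rates": {int(k): round(v, 4) for k, v in rates["mean"].items()}
        }

        stage = "zscore"
        Xz, zflags = zscore_within_responder(X, trials["responder"].to_numpy())
        if zflags:
            summary["exclusions"].append(
                {"stage": "zscore", "zero_variance_features": len(zflags)}
            )

        battery = decoder.task_battery()
        task_rows = []
        weight_rows = []
        for task_name in config.tasks:
            task = battery[task_name]
            if config.data_fraction < 1.0:
                from dataclasses import replace

                task = replace(task, data_fraction=config.data_fraction)
            for side in config.sides:
                stage = f"decode:{task_name}:{side}"
                run = decoder.run_task(
                    trials, Xz, task, side, config.lambda_grid, config.alpha,
                    config.min_per_class, seed=config.seed,
                )
                for r, reason in run.excluded:
                    summary["exclusions"].append(
                        {"stage": stage, "responder": r, "reason": reason}
                    )
                stage = f"nulls:{task_name}:{side}"
                shuffle_null = nulls.trial_shuffle_null(
                    trials, Xz, task, side, config.n_shuffles, config.seed,
                    config.lambda_grid, config.alpha, config.min_per_class,
                )
                guess_null = nulls.random_guess_null(
                    trials, Xz, task, side, config.n_guesses, config.seed,
                    config.min_per_class,
                )
                observed = run.median_balanced_accuracy
                p_shuffle = nulls.empirical_p(observed, shuffle_null)
                p_guess = nulls.empirical_p(observed, guess_null)
                pd.DataFrame(
                    {"shuffle": shuffle_null.samples}
                ).to_csv(out / f"null_shuffle_{task_name}_{side}.csv", index=False)
                for r, cv in run.results.items():
                    task_rows.append(
                        {"task": task_name, "side": side, "responder": r,
                         "balanced_accuracy": cv.balanced_accuracy,
                         "n_class0": cv.n_per_class[0], "n_class1": cv.n_per_class[1]}
                    )
                summary["stages"][f"{task_name}:{side}"] = {
                    "median_balanced_accuracy": round(observed, 4),
                    "n_responders": len(run.results),
                    "p_shuffle": p_shuffle,
                    "p_random_guess": p_guess,
                }

                if config.run_weights and task.test_offers is None:
                    stage = f"weights:{task_name}:{side}"
                    summaries = []
                    prepared, _ = decoder.prepare_task(
                        trials, Xz, task, side, config.min_per_class, config.seed
                    )
                    for r, cv in run.results.items():
                        ws = weights.aggregate_weights(
                            cv.fold_betas, responder_id=r, side=side, task=task_name
                        )
                        null_medians = weights.shuffle_median_weights(
                            prepared[r].X_train, prepared[r].y_train,
                            cv.fold_lambdas, n_shuffles=config.n_shuffles,
                            alpha=config.alpha, seed=config.seed,
                        )
                        ws = weights.weight_significance(
                            ws, null_medians, alpha=config.fdr_alpha
                        )
                        summaries.append(ws)
                        if len(summaries) <= 2:  # example weight maps
                            weights.plot_weight_map(
                                ws, out / f"weights_{task_name}_{side}_{r}.png"
                            )
                        for j, name in enumerate(FEATURE_NAMES):
                            weight_rows.append(
                                {"task": task_name, "side": side, "responder": r,
                                 "feature": name,
                                 "median_weight": ws.median_beta[j],
                                 "p": ws.p_values[j],
                                 "significant": bool(ws.significant[j])}
                            )
                    if len(summaries) >= 2:
                        sim = weights.weight_similarity_matrix(summaries)
                        ids = [s.responder_id for s in summaries]
                        pd.DataFrame(sim, index=ids, columns=ids).to_csv(
                            out / f"weight_similarity_{task_name}_{side}.csv"
                        )
                        conc = weights.concentration_test(
                            np.vstack([s.significant for s in summaries])
                        )
                        pd.DataFrame(
                            {"feature": list(FEATURE_NAMES), "x": conc.x,
                             "p_binom": conc.p_binom}
                        ).to_csv(
                            out / f"concentration_{task_name}_{side}.csv", index=False
                        )

        if task_rows:
            pd.DataFrame(task_rows).to_csv(out / "task_results.csv", index=False)
        if weight_rows:
            pd.DataFrame(weight_rows).to_csv(out / "weight_summaries.csv", index=False)

        if config.run_embedding:
            stage = "embedding"
            ug = ~trials["is_control"].astype(bool)
            if ug.sum() >= 3 * config.perplexity:
                emb = embedding.embed_2d(
                    Xz[ug.to_numpy()], config.perplexity, config.seed,
                    keys={
                        "responder": trials.loc[ug, "responder"].to_numpy(),
                        "choice": trials.loc[ug, "choice"].to_numpy(),
                        "fairness": trials.loc[ug, "fairness"].to_numpy(),
                    },
                )
                coords = pd.DataFrame(emb.coords, columns=["tsne_1", "tsne_2"])
                for key, vals in emb.keys.items():
                    coords[key] = vals
                coords.to_csv(out / "embedding.csv", index=False)
                for key in ("responder", "choice", "fairness"):
                    embedding.plot_embedding(emb, key, out / f"embedding_{key}.png")
    except Exception as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
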