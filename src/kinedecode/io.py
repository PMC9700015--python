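"""CSV readers and writers for the package's columnar schemas.

Schemas (all plain CSV, documented in the README):

* trial table — one row per trial:
  responder,session,trial,offer,accept_side,choice,side,is_control,fairness
* feature matrix — one row per trial:
  responder,trial,side,<variable>_<epoch>... in the canonical 170-column
  order of :data:`kinedecode.kinematics.FEATURE_NAMES` (bit-stable order)
* marker trajectory — one row per sample:
  time_s,<marker>_x,<marker>_y,<marker>_z (mm)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import FEATURE_NAMES, MarkerTrajectory


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"responder": str},
    )
    for col in ("offer", "choice"):
        df[col] = df[col].astype("Int64")
    return df


def write_features(
    trials: pd.DataFrame, X: np.ndarray, path
) -> None:
    """Feature matrix CSV with `responder,trial,side` key columns."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"feature matrix must have {len(FEATURE_NAMES)} columns")
    out = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    out.insert(0, "side", trials["side"].to_numpy())
    out.insert(0, "trial", trials["trial"].to_numpy())
    out.insert(0, "responder", trials["responder"].to_numpy())
    out.to_csv(path, index=False)


def read_features(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Returns (key frame with responder/trial/side, (n, 170) matrix)."""
    df = pd.read_csv(path, dtype={"responder": str})
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV is missing columns: {missing[:3]}...")
    keys = df[["responder", "trial", "side"]].copy()
    return keys, df[list(FEATURE_NAMES)].to_numpy(dtype=float)


def write_markers(traj: MarkerTrajectory, path) -> None:
    cols = {"time_s": traj.time}
    for name, pos in traj.markers.items():
        cols[f"{name}_x"] = pos[:, 0]
        cols[f"{name}_y"] = pos[:, 1]
        cols[f"{name}_z"] = pos[:, 2]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_markers(path, sampling_rate: float | None = None) -> MarkerTrajectory:
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        dt = np.diff(time)
        if dt.size == 0 or not np.allclose(dt, dt[0]):
            raise ValueError("cannot infer sampling rate from irregular time axis")
        sampling_rate = 1.0 / dt[0]
    names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    markers = {
        name: df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy(dtype=float)
        for name in names
    }
    return MarkerTrajectory(sampling_rate=float(sampling_rate), markers=markers, time=time)
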