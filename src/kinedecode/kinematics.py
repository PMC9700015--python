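"""From raw marker trajectories to 170-dimensional single-trial vectors.

The single-trial kinematic vector stacks 17 variables x 10 time epochs.
The 17 variables comprise a global set — wrist velocity (speed of the
radial wrist marker), the three wrist position components, grip aperture
(thumb-tip to index-tip distance) — and a local set expressed in a frame
centered on the hand: index-tip and thumb-tip coordinates, and the unit
normals of the finger plane (thu3, ind3, ind1) and of the hand-dorsum
plane (ind1, lit3, wrist).

Processing stages: 6 Hz zero-phase Butterworth low-pass on marker
positions; reach segmentation by the 20 mm/s wrist-speed threshold; the 17
variable series on the segment; time normalization to a percentage of
movement duration and reduction to 10 epoch means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.interpolate import CubicSpline

N_VARIABLES = 17
N_EPOCHS = 10
N_FEATURES = N_VARIABLES * N_EPOCHS

#: canonical variable order (variable-major feature layout)
VARIABLE_NAMES = (
    "wrist_velocity",
    "wrist_x", "wrist_y", "wrist_z",
    "grip_aperture",
    "index_x", "index_y", "index_z",
    "thumb_x", "thumb_y", "thumb_z",
    "finger_plane_x", "finger_plane_y", "finger_plane_z",
    "dorsum_plane_x", "dorsum_plane_y", "dorsum_plane_z",
)

#: canonical 170-column feature order: <variable>_<epoch percent>
FEATURE_NAMES = tuple(
    f"{var}_{(e + 1) * 10}" for var in VARIABLE_NAMES for e in range(N_EPOCHS)
)

SPEED_THRESHOLD_MM_S = 20.0

REQUIRED_MARKERS = ("radio", "wrist", "thu3", "ind3", "ind1", "lit3")


class NoMovementError(RuntimeError):
    """Wrist speed never crosses the segmentation threshold."""


class MissingMarkerError(KeyError):
    """A marker required by the variable set is absent."""


@dataclass
class MarkerTrajectory:
    """Time-sampled 3-D marker positions (mm) for one trial."""

    sampling_rate: float
    markers: dict[str, np.ndarray]
    time: np.ndarray | None = None
    events: dict | None = None

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {m.shape[0] for m in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError("all marker series must have equal length")
        (self.n_samples,) = lengths or {0}
        if self.time is None:
            self.time = np.arange(self.n_samples) / self.sampling_rate

    def require(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise MissingMarkerError(f"required marker '{name}' is missing") from None


@dataclass
class ReachSegment:
    onset: int
    offset: int
    sampling_rate: float

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / self.sampling_rate

    @property
    def slice(self) -> slice:
        return slice(self.onset, self.offset + 1)


@dataclass
class KinematicSeries:
    """The 17 named variable series over the reach segment."""

    variables: dict[str, np.ndarray]
    sampling_rate: float

    def __post_init__(self):
        if tuple(self.variables) != VARIABLE_NAMES:
            raise ValueError(f"expected exactly the {N_VARIABLES} canonical variables")


@dataclass
class FeatureVector:
    """170 ordered values: (variable 1..17) x (epoch 10%..100%)."""

    values: np.ndarray
    responder_id: str | None = None
    trial_index: int | None = None
    side: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")


def lowpass_filter(
    series: np.ndarray, sampling_rate: float, cutoff: float = 6.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward-backward).

    The forward-backward application avoids phase lag that would bias the
    timing of threshold-crossing events; the effective magnitude response
    is the squared order-``order`` Butterworth gain.
    """
    series = np.asarray(series, dtype=float)
    sos = _signal.butter(order, cutoff, fs=sampling_rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if series.shape[0] <= padlen:
        raise ValueError(
            f"series too short for order-{order} zero-phase filtering "
            f"(need > {padlen} samples)"
        )
    return _signal.sosfiltfilt(sos, series, axis=0)


def filter_trajectory(traj: MarkerTrajectory, cutoff: float = 6.0, order: int = 2) -> MarkerTrajectory:
    return MarkerTrajectory(
        sampling_rate=traj.sampling_rate,
        markers={
            name: lowpass_filter(pos, traj.sampling_rate, cutoff, order)
            for name, pos in traj.markers.items()
        },
        time=traj.time,
        events=traj.events,
    )


def wrist_speed(traj: MarkerTrajectory, marker: str = "radio") -> np.ndarray:
    """Magnitude of the 3-D velocity of the (radial) wrist marker, mm/s.

    Velocity by central differences on the position series.
    """
    pos = traj.require(marker)
    vel = np.gradient(pos, 1.0 / traj.sampling_rate, axis=0)
    return np.linalg.norm(vel, axis=1)


def segment_reach(
    speed: np.ndarray,
    sampling_rate: float,
    threshold: float = SPEED_THRESHOLD_MM_S,
    min_rest_s: float = 0.1,
) -> ReachSegment:
    """Bound the reach by the 20 mm/s wrist-speed crossings.

    Onset: first sample at or above threshold.  Offset: last sample at or
    above threshold before the speed stays below threshold for at least
    ``min_rest_s`` (robust to brief corrective re-crossings); if the speed
    never rests that long, the last above-threshold sample is used.
    """
    speed = np.asarray(speed, dtype=float)
    above = speed >= threshold
    if not above.any():
        raise NoMovementError("wrist speed never crossed the movement threshold")
    onset = int(np.flatnonzero(above)[0])
    min_rest = max(1, int(round(min_rest_s * sampling_rate)))
    offset = None
    i = onset
    n = speed.size
    while i < n:
        if above[i]:
            i += 1
            continue
        # below-threshold run starting at i
        j = i
        while j < n and not above[j]:
            j += 1
        if (j - i) >= min_rest or j == n:
            offset = i - 1
            break
        i = j
    if offset is None:
        offset = int(np.flatnonzero(above)[-1])
    return ReachSegment(onset=onset, offset=offset, sampling_rate=sampling_rate)


def _hand_frame(traj: MarkerTrajectory, sl: slice):
    """Per-sample orthonormal hand frame.

    Origin at the wrist marker; primary axis wrist -> ind1; the plane is
    spanned with lit3; right-handed orthonormalization.  Returns
    (origin (n,3), rotation (n,3,3)) with rows = frame axes.
    """
    w = traj.require("wrist")[sl]
    i1 = traj.require("ind1")[sl]
    l3 = traj.require("lit3")[sl]
    x = i1 - w
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    aux = l3 - w
    z = np.cross(x, aux)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=1)
    return w, R


def _to_local(points: np.ndarray, origin: np.ndarray, R: np.ndarray) -> np.ndarray:
    return np.einsum("nij,nj->ni", R, points - origin)


def _plane_normal_series(p1, p2, p3, sign_ref):
    """Unit normal of the (p1, p2, p3) plane over time.

    The sign is fixed at the first sample so the normal points along
    ``sign_ref`` (away from the palm), then kept temporally continuous.
    """
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("degenerate (collinear) plane markers")
    n = n / norm
    if np.dot(n[0], sign_ref) < 0:
        n = -n
    flips = np.einsum("ni,ni->n", n[1:], n[:-1]) < 0
    sign = np.concatenate([[1.0], np.where(flips, -1.0, 1.0)]).cumprod()
    return n * sign[:, None]


def compute_variable_set(traj: MarkerTrajectory, segment: ReachSegment) -> KinematicSeries:
    """All 17 variables on the reach segment."""
    sl = segment.slice
    for m in REQUIRED_MARKERS:
        traj.require(m)
    speed = wrist_speed(traj)[sl]
    radio = traj.markers["radio"][sl]
    thu3 = traj.markers["thu3"][sl]
    ind3 = traj.markers["ind3"][sl]
    ind1 = traj.markers["ind1"][sl]
    lit3 = traj.markers["lit3"][sl]
    wrist = traj.markers["wrist"][sl]

    aperture = np.linalg.norm(thu3 - ind3, axis=1)
    origin, R = _hand_frame(traj, sl)
    ind3_loc = _to_local(ind3, origin, R)
    thu3_loc = _to_local(thu3, origin, R)
    z_hand0 = R[0, 2]
    finger_n = _plane_normal_series(thu3, ind3, ind1, z_hand0)
    dorsum_n = _plane_normal_series(ind1, lit3, wrist, z_hand0)

    v = {
        "wrist_velocity": speed,
        "wrist_x": radio[:, 0], "wrist_y": radio[:, 1], "wrist_z": radio[:, 2],
        "grip_aperture": aperture,
        "index_x": ind3_loc[:, 0], "index_y": ind3_loc[:, 1], "index_z": ind3_loc[:, 2],
        "thumb_x": thu3_loc[:, 0], "thumb_y": thu3_loc[:, 1], "thumb_z": thu3_loc[:, 2],
        "finger_plane_x": finger_n[:, 0], "finger_plane_y": finger_n[:, 1],
        "finger_plane_z": finger_n[:, 2],
        "dorsum_plane_x": dorsum_n[:, 0], "dorsum_plane_y": dorsum_n[:, 1],
        "dorsum_plane_z": dorsum_n[:, 2],
    }
    ordered = {name: np.ascontiguousarray(v[name], dtype=float) for name in VARIABLE_NAMES}
    return KinematicSeries(variables=ordered, sampling_rate=segment.sampling_rate)


def time_normalize_epochs(
    series: KinematicSeries, n_points: int = 101
) -> np.ndarray:
    """Reduce each variable to 10 epoch means over % movement duration.

    Each variable is resampled by cubic interpolation onto ``n_points``
    equally spaced points of normalized time, then averaged within each
    decile (0-10%, ..., 90-100%).  Returns the 170-vector in the canonical
    variable-major order.
    """
    out = np.empty(N_FEATURES)
    grid = np.linspace(0.0, 1.0, n_points)
    per_epoch = (n_points - 1) // N_EPOCHS
    for vi, name in enumerate(VARIABLE_NAMES):
        x = series.variables[name]
        if x.size < N_EPOCHS:
            raise ValueError(
                f"variable '{name}' has fewer samples ({x.size}) than epochs"
            )
        t = np.linspace(0.0, 1.0, x.size)
        if x.size >= 4:
            resampled = CubicSpline(t, x)(grid)
        else:
            resampled = np.interp(grid, t, x)
        for e in range(N_EPOCHS):
            seg = resampled[e * per_epoch : (e + 1) * per_epoch + 1]
            out[vi * N_EPOCHS + e] = seg.mean()
    return out


def extract_features(
    traj: MarkerTrajectory,
    cutoff: float = 6.0,
    order: int = 2,
    threshold: float = SPEED_THRESHOLD_MM_S,
    responder_id: str | None = None,
    trial_index: int | None = None,
    side: str | None = None,
) -> FeatureVector:
    """Full pipeline: filter, segment, variables, epochs -> 170 features."""
    filt = filter_trajectory(traj, cutoff=cutoff, order=order)
    speed = wrist_speed(filt)
    segment = segment_reach(speed, traj.sampling_rate, threshold=threshold)
    series = compute_variable_set(filt, segment)
    values = time_normalize_epochs(series)
    return FeatureVector(
        values=values, responder_id=responder_id, trial_index=trial_index, side=side
    )


def zscore_within_responder(
    X: np.ndarray, responders: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Standardize each feature to mean 0, SD 1 within each responder.

    Zero-variance features are set to 0 and reported in the returned flag
    list (responder, feature index).  SD uses the n-1 convention.
    """
    X = np.asarray(X, dtype=float)
    responders = np.asarray(responders)
    out = np.empty_like(X)
    flags: list[tuple[str, int]] = []
    for r in np.unique(responders):
        mask = responders == r
        if mask.sum() < 2:
            raise ValueError(f"responder {r!r} has fewer than 2 trials")
        block = X[mask]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=ddof)
        zero = sd == 0
        sd_safe = np.where(zero, 1.0, sd)
        out[mask] = (block - mu) / sd_safe
        if zero.any():
            out[np.ix_(mask, zero)] = 0.0
            flags.extend((str(r), int(j)) for j in np.flatnonzero(zero))
    return out, flags
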