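"""Synthetic motor Ultimatum Game data.

Generates responders, trial designs, single-trial kinematic feature vectors
and raw marker trajectories with the statistical structure the decoding
analysis assumes, so the whole pipeline can run end to end without any
external data.

The emulated design: each session holds 68 Ultimatum Game trials (12 offers
each of EUR 1-3 and 16 each of EUR 4-5) plus 12 control trials (6 per
side), fully randomized in order; the 'accept' cylinder side swaps between
the two sessions, so each movement direction accumulates both accept and
reject trials across sessions.  Choices are Bernoulli draws from a
monotone offer -> acceptance-probability curve.  Feature vectors follow an
additive model: a responder-specific baseline plus choice- and
fairness-dependent effect vectors plus i.i.d. Gaussian trial noise.
Mid-range offers (EUR 3) contribute no fairness term.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import N_FEATURES, MarkerTrajectory

OFFER_LEVELS = (1, 2, 3, 4, 5)
OFFER_COUNTS = {1: 12, 2: 12, 3: 12, 4: 16, 5: 16}
N_UG_TRIALS_PER_SESSION = 68
N_CONTROL_PER_SIDE = 6
FAIR_OFFERS = (4, 5)
UNFAIR_OFFERS = (1, 2)
MID_OFFER = 3
SIDES = ("left", "right")

#: Published group-mean acceptance rates per offer level (fractions).
GROUP_ACCEPTANCE_RATES = {1: 0.134, 2: 0.363, 3: 0.646, 4: 0.9613, 5: 0.984}


def default_accept_curve() -> dict[int, float]:
    """Logistic-in-offer acceptance curve calibrated to the group means.

    A straight line is least-squares fitted to the logits of
    :data:`GROUP_ACCEPTANCE_RATES` and mapped back through the sigmoid, so
    the curve is monotone in offer value by construction.
    """
    offers = np.array(sorted(GROUP_ACCEPTANCE_RATES))
    rates = np.array([GROUP_ACCEPTANCE_RATES[o] for o in offers])
    logits = np.log(rates / (1.0 - rates))
    slope, intercept = np.polyfit(offers, logits, 1)
    return {
        int(o): float(1.0 / (1.0 + np.exp(-(intercept + slope * o))))
        for o in offers
    }


@dataclass
class TrialRecord:
    """One game trial's metadata and labels.

    ``accept_side`` is the side of the 'accept' cylinder in the trial's
    session; ``side`` is the movement direction actually executed (the side
    of the grasped cylinder), which for game trials is only known once the
    choice is made.  Control trials carry no offer/choice semantics and
    have their side instructed at design time.
    """

    responder_id: str
    session: int
    trial_index: int
    offer: int | None
    accept_side: str | None
    is_control: bool = False
    choice: int | None = None  # 1 = accept, 0 = reject
    side: str | None = None

    @property
    def fairness_label(self) -> str | None:
        if self.is_control or self.offer is None:
            return None
        if self.offer in FAIR_OFFERS:
            return "fair"
        if self.offer in UNFAIR_OFFERS:
            return "unfair"
        return "mid"


@dataclass
class MotorParams:
    """Reach-to-grasp generative parameters (mm, s)."""

    duration_s: float = 1.0
    peak_aperture_mm: float = 90.0
    start_aperture_mm: float = 30.0
    final_aperture_mm: float = 70.0
    aperture_peak_frac: float = 0.7
    lift_height_mm: float = 120.0
    target_distance_mm: float = 440.0
    target_lateral_mm: float = 180.0
    rest_pad_s: float = 0.3
    noise_mm: float = 0.3
    sampling_rate: float = 100.0


@dataclass
class ResponderProfile:
    """Generative description of one synthetic responder."""

    responder_id: str
    baseline_mu: np.ndarray
    beta_choice: np.ndarray
    beta_fair: np.ndarray
    noise_sd: float | np.ndarray = 1.0
    accept_curve: dict[int, float] = field(default_factory=default_accept_curve)
    motor_params: MotorParams = field(default_factory=MotorParams)

    def __post_init__(self):
        for name in ("baseline_mu", "beta_choice", "beta_fair"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_FEATURES,):
                raise ValueError(f"{name} must have length {N_FEATURES}")
            setattr(self, name, v)
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValueError("noise_sd must be positive")
        probs = [self.accept_curve[o] for o in sorted(self.accept_curve)]
        if np.any(np.diff(probs) < 0):
            raise ValueError("acceptance probability must be non-decreasing in offer")


def make_profile(
    responder_id: str,
    seed: int | np.random.SeedSequence,
    effect_scale: float = 0.8,
    fairness_scale: float | None = None,
    sparsity: float = 0.1,
    noise_sd: float = 1.0,
    baseline_scale: float = 2.0,
    accept_curve: dict[int, float] | None = None,
    motor_params: MotorParams | None = None,
) -> ResponderProfile:
    """Draw an idiosyncratic responder.

    Effect vectors are sparse (``sparsity`` fraction of nonzero features,
    mirroring the sparse weight maps the decoder recovers) with entries of
    magnitude ``effect_scale`` and random sign.  ``effect_scale = 0`` gives
    a zero-signal responder for calibration studies.
    """
    rng = np.random.default_rng(seed)
    if fairness_scale is None:
        fairness_scale = effect_scale
    k = max(1, int(round(sparsity * N_FEATURES)))
    baseline = rng.normal(0.0, baseline_scale, N_FEATURES)

    def sparse_effect(scale):
        v = np.zeros(N_FEATURES)
        if scale != 0.0:
            idx = rng.choice(N_FEATURES, size=k, replace=False)
            v[idx] = rng.choice([-1.0, 1.0], size=k) * scale
        return v

    return ResponderProfile(
        responder_id=responder_id,
        baseline_mu=baseline,
        beta_choice=sparse_effect(effect_scale),
        beta_fair=sparse_effect(fairness_scale),
        noise_sd=noise_sd,
        accept_curve=dict(accept_curve) if accept_curve else default_accept_curve(),
        motor_params=motor_params or MotorParams(),
    )


def make_cohort(n_responders: int, seed: int, **profile_kwargs) -> list[ResponderProfile]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_responders)
    return [
        make_profile(f"r{i:02d}", child, **profile_kwargs)
        for i, child in enumerate(children)
    ]


def make_design(
    n_sessions: int, seed: int, responder_id: str = "r00"
) -> list[TrialRecord]:
    """Build the randomized trial schedule for one responder.

    Each session: the fixed per-offer counts plus 12 control trials (6 per
    side); the accept-cylinder side alternates between sessions (left on
    odd sessions); trial order is randomized by ``seed``.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    index = 0
    for session in range(1, n_sessions + 1):
        accept_side = "left" if session % 2 == 1 else "right"
        session_trials: list[TrialRecord] = []
        for offer, count in OFFER_COUNTS.items():
            for _ in range(count):
                session_trials.append(
                    TrialRecord(responder_id, session, -1, offer, accept_side)
                )
        for side in SIDES:
            for _ in range(N_CONTROL_PER_SIDE):
                session_trials.append(
                    TrialRecord(
                        responder_id, session, -1, None, accept_side,
                        is_control=True, side=side,
                    )
                )
        order = rng.permutation(len(session_trials))
        for pos in order:
            t = session_trials[pos]
            t.trial_index = index
            index += 1
            trials.append(t)
    return trials


def _other_side(side: str) -> str:
    return "left" if side == "right" else "right"


def simulate_choices(
    profile: ResponderProfile, design: list[TrialRecord], seed: int
) -> list[TrialRecord]:
    """Fill choices (Bernoulli in the offer's acceptance probability).

    The movement side follows from the choice and the session's
    accept-cylinder side.  Control trials pass through unchanged.
    """
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(design)
    for t in out:
        if t.is_control:
            continue
        if t.offer is None:
            raise ValueError(
                f"non-control trial {t.trial_index} is missing an offer"
            )
        p = profile.accept_curve[t.offer]
        t.choice = int(rng.random() < p)
        t.side = t.accept_side if t.choice == 1 else _other_side(t.accept_side)
    return out


def simulate_features(
    profile: ResponderProfile, trials: list[TrialRecord], seed: int
) -> np.ndarray:
    """Single-trial feature matrix (n_trials, 170), aligned with ``trials``.

    K = baseline + 1[accept] * beta_choice + 1[fair] * beta_fair + noise.
    Control trials receive baseline + noise only.
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    X = np.tile(profile.baseline_mu, (n, 1))
    for i, t in enumerate(trials):
        if t.is_control:
            continue
        if t.choice is None:
            raise ValueError(f"trial {t.trial_index} has no simulated choice")
        if t.choice == 1:
            X[i] += profile.beta_choice
        if t.fairness_label == "fair":
            X[i] += profile.beta_fair
    X += rng.normal(0.0, 1.0, (n, N_FEATURES)) * np.asarray(profile.noise_sd)
    return X


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _min_jerk_rate(tau: np.ndarray) -> np.ndarray:
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


# rigid marker offsets relative to the wrist, mm (hand kept unrotated)
_HAND_OFFSETS = {
    "wrist": (0.0, 0.0, 0.0),
    "radio": (12.0, 10.0, 6.0),
    "ulna": (-12.0, 8.0, 6.0),
    "palm": (0.0, 45.0, -5.0),
    "ind1": (15.0, 85.0, 0.0),
    "lit3": (-35.0, 65.0, -5.0),
}
_GRASP_OFFSET = np.array([12.0, 115.0, -10.0])
_APERTURE_AXIS = np.array([0.8, 0.0, 0.6]) / np.hypot(0.8, 0.6)


def simulate_markers(
    profile: ResponderProfile, trial: TrialRecord, seed: int
) -> MarkerTrajectory:
    """Raw 100 Hz marker trajectories for one reach-to-grasp trial.

    Wrist transport is a minimum-jerk translation toward the side-appropriate
    target with a bell-shaped speed profile and a sinusoidal lift; grip
    aperture opens to its peak (minimum-jerk segments) and closes onto the
    cylinder; i.i.d. Gaussian measurement noise is added to every marker.
    The returned trajectory carries the planted ground-truth events
    (threshold-crossing onset/offset sample, peak aperture) in ``events``.
    """
    mp = profile.motor_params
    if mp.duration_s <= 0:
        raise ValueError("movement duration must be positive")
    if trial.side not in SIDES:
        raise ValueError("trial has no movement side; simulate choices first")
    rng = np.random.default_rng(seed)
    fs = mp.sampling_rate
    n_pad = int(round(mp.rest_pad_s * fs))
    n_move = int(round(mp.duration_s * fs)) + 1
    n = 2 * n_pad + n_move
    time = np.arange(n) / fs

    tau = np.zeros(n)
    tau[n_pad : n_pad + n_move] = np.linspace(0.0, 1.0, n_move)
    tau[n_pad + n_move :] = 1.0
    s = _min_jerk(tau)

    sx = -1.0 if trial.side == "left" else 1.0
    start = np.zeros(3)
    target = np.array([sx * mp.target_lateral_mm, mp.target_distance_mm, 0.0])
    wrist = start + np.outer(s, target - start)
    wrist[:, 2] += mp.lift_height_mm * np.sin(np.pi * s)

    # planted wrist speed (analytic, noise-free) for ground-truth events
    moving = (tau > 0) & (tau < 1)
    rate = np.zeros(n)
    rate[moving] = _min_jerk_rate(tau[moving]) / mp.duration_s
    planar = np.linalg.norm(target - start)
    vz = mp.lift_height_mm * np.pi * np.cos(np.pi * s)
    speed = rate * np.sqrt(planar**2 + vz**2)
    above = np.flatnonzero(speed >= 20.0)
    events = {
        "onset_index": int(above[0]),
        "offset_index": int(above[-1]),
        "duration_s": float((above[-1] - above[0]) / fs),
        "peak_aperture_mm": mp.peak_aperture_mm,
    }

    # grip aperture: open to peak at aperture_peak_frac, then close
    ap = np.empty(n)
    tp = mp.aperture_peak_frac
    opening = tau <= tp
    ap[opening] = mp.start_aperture_mm + (
        mp.peak_aperture_mm - mp.start_aperture_mm
    ) * _min_jerk(tau[opening] / tp)
    ap[~opening] = mp.peak_aperture_mm + (
        mp.final_aperture_mm - mp.peak_aperture_mm
    ) * _min_jerk((tau[~opening] - tp) / (1.0 - tp))

    markers: dict[str, np.ndarray] = {}
    for name, off in _HAND_OFFSETS.items():
        markers[name] = wrist + np.asarray(off)
    grasp = wrist + _GRASP_OFFSET
    markers["ind3"] = grasp + 0.5 * ap[:, None] * _APERTURE_AXIS
    markers["thu3"] = grasp - 0.5 * ap[:, None] * _APERTURE_AXIS
    if mp.noise_mm > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, mp.noise_mm, (n, 3))

    return MarkerTrajectory(
        sampling_rate=fs, markers=markers, time=time, events=events
    )


def trials_to_frame(trials: list[TrialRecord]):
    """Tidy trial table (one row per trial)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "responder": [t.responder_id for t in trials],
            "session": [t.session for t in trials],
            "trial": [t.trial_index for t in trials],
            "offer": [t.offer for t in trials],
            "accept_side": [t.accept_side for t in trials],
            "choice": [t.choice for t in trials],
            "side": [t.side for t in trials],
            "is_control": [t.is_control for t in trials],
            "fairness": [t.fairness_label for t in trials],
        }
    )


def simulate_dataset(
    profiles: list[ResponderProfile], n_sessions: int = 2, seed: int = 0
):
    """Design + choices + features for a cohort.

    Returns ``(trials_df, X)`` with rows aligned.
    """
    import pandas as pd

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    frames = []
    mats = []
    for profile, child in zip(profiles, ss.spawn(len(profiles))):
        s_design, s_choice, s_feat = child.spawn(3)
        design = make_design(n_sessions, s_design, profile.responder_id)
        trials = simulate_choices(profile, design, s_choice)
        X = simulate_features(profile, trials, s_feat)
        frames.append(trials_to_frame(trials))
        mats.append(X)
    return pd.concat(frames, ignore_index=True), np.vstack(mats)
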