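"""Synthetic datasets: trials, responses, eye traces, and model neurons.

These generators instantiate the observer model as a generative process so
the full analysis pipeline is testable end to end without any recorded
data.  Defaults follow the psychophysical designs they emulate:

* Direction-report experiment: retinal directions -90..270 deg in 30 deg
  steps, 7 repetitions, interleaved R / R+T / no-background x Pursuit /
  Fixation conditions, both eye directions; reports are the observer-model
  prediction plus von Mises circular noise, with occasional uniform lapses.
* Depth-report experiment: directions -90..90 deg in 15 deg steps, 20
  repetitions; binary near/far reports are Bernoulli draws through a
  cumulative-Gaussian link on the predicted relative depth, with a fixed
  response bias (default toward "near") wherever depth is ambiguous.
* Eye traces: gaze = pursuit-gain-scaled target position plus smoothed
  positional noise and injected step-like catch-up saccades that exceed the
  40 deg/s cleaning threshold.
* Model neurons: Poisson spike counts on a retinal x eye velocity grid from
  the parametric joint-tuning rate model.

Object and eye speeds default to the mean speeds of the Gaussian stimulus
profiles (2.67 and 5.3 deg/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import direction_to_velocity, gaussian_velocity_profile
from .observer import (
    AmbiguousDepthError,
    EyeCondition,
    GeometryCondition,
    ObserverParams,
    predict_depth,
    predict_direction,
    slip_correct,
    TrialStimulus,
)
from .behavior import TRIAL_COLUMNS, EyeTrace

__all__ = [
    "Experiment",
    "ExperimentDesign",
    "SyntheticObserverSpec",
    "default_condition_params",
    "default_cohort",
    "generate_trials",
    "generate_eye_traces",
    "generate_mt_neurons",
]


class Experiment(str, Enum):
    EXP1 = "Exp1"  # direction estimation
    EXP2 = "Exp2"  # near/far depth discrimination


@dataclass
class ExperimentDesign:
    """Trial design of one experiment."""

    experiment: Experiment = Experiment.EXP1
    directions: np.ndarray = None
    reps: int = 7
    conditions: tuple = (
        (GeometryCondition.R, EyeCondition.PURSUIT),
        (GeometryCondition.R, EyeCondition.FIXATION),
        (GeometryCondition.RT, EyeCondition.PURSUIT),
        (GeometryCondition.RT, EyeCondition.FIXATION),
        (GeometryCondition.NONE, EyeCondition.PURSUIT),
        (GeometryCondition.NONE, EyeCondition.FIXATION),
    )
    eye_speed: float = 5.3
    retinal_speed: float = 2.67

    def __post_init__(self) -> None:
        self.experiment = Experiment(self.experiment)
        if self.directions is None:
            if self.experiment == Experiment.EXP1:
                self.directions = np.arange(-90.0, 271.0, 30.0)
            else:
                self.directions = np.arange(-90.0, 91.0, 15.0)
        self.directions = np.asarray(self.directions, dtype=float)

    @classmethod
    def exp1(cls, **kw) -> "ExperimentDesign":
        return cls(experiment=Experiment.EXP1, reps=kw.pop("reps", 7), **kw)

    @classmethod
    def exp2(cls, **kw) -> "ExperimentDesign":
        return cls(experiment=Experiment.EXP2, reps=kw.pop("reps", 20), **kw)


def default_condition_params(
    a_ret_R: float = 0.0,
    a_eye_R: float = 0.4,
    a_ret_RT: float = 0.3,
    a_eye_RT: float = 0.1,
    g_pursuit: float = 0.85,
) -> dict:
    """Observer parameters per condition, near the group tendencies.

    In the pure-rotation interpretation the eye velocity is partially added
    back (a_eye > 0, a_ret ~ 0); in the fixation-pivot interpretation part
    of the horizontal retinal motion is parsed as parallax (a_ret > 0).
    The control condition (no background) is the identity observer.
    """
    out = {}
    for eye_cond in EyeCondition:
        out[(GeometryCondition.R, eye_cond)] = ObserverParams(
            g_ret=a_ret_R, g_eye=min(a_eye_R, 1.0), a_ret=a_ret_R, a_eye=a_eye_R,
            g_pursuit=g_pursuit,
        )
        out[(GeometryCondition.RT, eye_cond)] = ObserverParams(
            g_ret=a_ret_RT, g_eye=1.0, a_ret=a_ret_RT, a_eye=a_eye_RT,
            g_pursuit=g_pursuit,
        )
        out[(GeometryCondition.NONE, eye_cond)] = ObserverParams(
            g_ret=0.0, g_eye=0.0, a_ret=0.0, a_eye=0.0, g_pursuit=g_pursuit,
        )
    return out


@dataclass
class SyntheticObserverSpec:
    """A synthetic participant: per-condition observer params plus noise."""

    params: dict = field(default_factory=default_condition_params)
    report_noise_kappa: float = 20.0
    depth_noise_sigma: float = 0.3
    lapse: float = 0.02
    depth_prior_bias: float = 0.8  # P("near") under ambiguous depth
    participant_id: str = "s000"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.report_noise_kappa <= 0:
            raise ValueError("report_noise_kappa must be positive")
        for name in ("lapse", "depth_prior_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def default_cohort(n: int = 10, seed: int | None = None) -> list[SyntheticObserverSpec]:
    """A cohort of synthetic participants with dispersed observer weights.

    Weights are drawn around the group tendencies (R: a_eye ~ 0.4,
    a_ret ~ 0; R+T: a_ret ~ 0.3, a_eye ~ 0.1) with SD 0.1, clipped to
    [0, 1], so group statistics are exercisable.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        draw = lambda mu: float(np.clip(rng.normal(mu, 0.1), 0.0, 1.0))
        params = default_condition_params(
            a_ret_R=draw(0.02),
            a_eye_R=draw(0.4),
            a_ret_RT=draw(0.3),
            a_eye_RT=draw(0.1),
            g_pursuit=float(np.clip(rng.normal(0.85, 0.1), 0.4, 1.1)),
        )
        cohort.append(
            SyntheticObserverSpec(
                params=params,
                report_noise_kappa=20.0,
                depth_noise_sigma=float(rng.uniform(0.2, 0.5)),
                lapse=0.02,
                depth_prior_bias=float(rng.uniform(0.6, 0.95)),
                participant_id=f"s{i:03d}",
                seed=int(rng.integers(2**31)),
            )
        )
    return cohort


def generate_trials(
    design: ExperimentDesign, observer: SyntheticObserverSpec
) -> pd.DataFrame:
    """Simulate a full session of one synthetic participant.

    Each (condition, eye sign, direction) cell is repeated ``design.reps``
    times in a seed-controlled shuffled order.  Direction reports get von
    Mises noise (concentration ``report_noise_kappa``) and uniform lapses;
    depth reports are Bernoulli through a cumulative-Gaussian link,
    ``P(far) = Phi(d_hat' / depth_noise_sigma)``, or the prior bias when
    depth is ambiguous.
    """
    rng = np.random.default_rng(observer.seed)
    rows = []
    for geometry, eye_cond in design.conditions:
        params = observer.params[(GeometryCondition(geometry), EyeCondition(eye_cond))]
        for eye_dir in (-1.0, 1.0):
            for direction in design.directions:
                for _ in range(design.reps):
                    rows.append((geometry, eye_cond, eye_dir, float(direction), params))
    order = rng.permutation(len(rows))
    records = []
    for k in order:
        geometry, eye_cond, eye_dir, direction, params = rows[k]
        stim = TrialStimulus(
            retinal_velocity=tuple(direction_to_velocity(direction, design.retinal_speed)),
            eye_velocity_x=eye_dir * design.eye_speed,
            geometry_condition=GeometryCondition(geometry),
            eye_condition=EyeCondition(eye_cond),
        )
        # physical slip: the executed pursuit has gain g_pursuit, so the true
        # retinal/eye velocities differ from the intended ones
        eye_x, ret = slip_correct(stim, params.g_pursuit)
        report_dir = np.nan
        depth_report = None
        if design.experiment == Experiment.EXP1:
            predicted = predict_direction(ret, eye_x, params)
            if rng.random() < observer.lapse:
                report_dir = float(rng.uniform(-90.0, 270.0))
            else:
                noise = rng.vonmises(0.0, observer.report_noise_kappa)
                report_dir = float(predicted + np.rad2deg(noise))
                report_dir = (report_dir + 90.0) % 360.0 - 90.0
        else:
            if GeometryCondition(geometry) == GeometryCondition.R:
                p_far = 1.0 - observer.depth_prior_bias
            else:
                try:
                    dhat = predict_depth(ret[0], eye_x, params)
                    p_far = float(norm.cdf(dhat / observer.depth_noise_sigma))
                except AmbiguousDepthError:
                    p_far = 1.0 - observer.depth_prior_bias
            if rng.random() < observer.lapse:
                p_far = 0.5
            depth_report = "far" if rng.random() < p_far else "near"
        records.append(
            {
                "participant": observer.participant_id,
                "experiment": design.experiment.value,
                "geometry": GeometryCondition(geometry).value,
                "eye_condition": EyeCondition(eye_cond).value,
                "eye_dir": eye_dir,
                "retinal_dir_deg": direction,
                "retinal_speed_deg_s": design.retinal_speed,
                "eye_speed_deg_s": design.eye_speed,
                "report_dir_deg": report_dir,
                "depth_report": depth_report,
                "valid": True,
            }
        )
    return pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)


def generate_eye_traces(
    n_trials: int = 20,
    g_pursuit_true: float = 0.85,
    noise_sd: float = 0.1,
    saccade_rate: float = 0.0,
    seed: int | None = None,
    displacement_deg: float = 5.3,
    duration_s: float = 1.0,
    sample_rate: float = 1000.0,
) -> tuple[list[EyeTrace], "np.ndarray"]:
    """Synthetic pursuit traces with imperfect gain and catch-up saccades.

    Gaze follows ``g_pursuit_true`` times the target position (Gaussian
    velocity profile spanning the trial) plus low-pass positional noise.
    Saccades are injected as brief (~20 ms) position steps of 0.5-1.5 deg,
    at an average of ``saccade_rate`` per second, producing velocities far
    above the 40 deg/s cleaning threshold.

    Returns the traces and the target velocity profile used.
    """
    if g_pursuit_true < 0:
        raise ValueError("g_pursuit_true must be >= 0")
    rng = np.random.default_rng(seed)
    profile = gaussian_velocity_profile(displacement_deg, duration_s, sample_rate)
    target = profile.position()
    n = len(target)
    traces = []
    for _ in range(n_trials):
        gaze = g_pursuit_true * target
        if noise_sd > 0:
            white = rng.normal(0.0, 1.0, n)
            kern = np.exp(-0.5 * (np.arange(-150, 151) / 50.0) ** 2)
            kern /= kern.sum()
            smooth = np.convolve(np.pad(white, 150, mode="reflect"), kern, "valid")
            gaze = gaze + noise_sd * smooth / max(np.std(smooth), 1e-12)
        n_sacc = rng.poisson(saccade_rate * duration_s)
        for _ in range(n_sacc):
            onset = rng.integers(0, max(n - 25, 1))
            amp = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            ramp = np.linspace(0.0, amp, 20)
            step = np.concatenate([np.zeros(onset), ramp, np.full(n - onset - 20, amp)])
            gaze = gaze + step[:n]
        t = np.arange(n) / sample_rate
        traces.append(
            EyeTrace(
                time=t,
                gaze_x=gaze,
                gaze_y=np.zeros(n),
                target_x=target,
                sample_rate=sample_rate,
            )
        )
    return traces, profile


def generate_mt_neurons(
    true_params: list,
    grid: np.ndarray | None = None,
    trials_per_cell: int = 20,
    seed: int | None = None,
    count_window_s: float = 1.0,
) -> pd.DataFrame:
    """Poisson spike-count tables from the joint-tuning rate model.

    One row per (neuron, v_retina, v_eye, trial); counts are Poisson with
    mean ``rate * count_window_s``.
    """
    from .mt import firing_rate

    if grid is None:
        grid = np.arange(-10.0, 10.1, 2.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    vr, ve = np.meshgrid(grid, grid, indexing="ij")
    records = []
    for ni, params in enumerate(true_params):
        lam = firing_rate(vr, ve, params) * count_window_s
        counts = rng.poisson(np.broadcast_to(lam, (trials_per_cell,) + lam.shape))
        for ti in range(trials_per_cell):
            for a in range(len(grid)):
                for b in range(len(grid)):
                    records.append(
                        (ni, float(grid[a]), float(grid[b]), ti, int(counts[ti, a, b]))
                    )
    return pd.DataFrame.from_records(
        records, columns=["neuron", "v_retina", "v_eye", "trial", "count"]
    )
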