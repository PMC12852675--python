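"""Fitting behavioral data: observer weights, psychometrics, eye traces, stats.

Trial tables are pandas DataFrames with the columns

    participant, experiment, geometry, eye_condition, eye_dir,
    retinal_dir_deg, retinal_speed_deg_s, eye_speed_deg_s,
    report_dir_deg, depth_report, valid

(exactly one of ``report_dir_deg`` / ``depth_report`` populated per row;
``depth_report`` coded "near"/"far"; invalid trials are excluded from every
fit).  Eye traces are per-trial series of gaze and target position.

The observer-weight fit minimizes the mean cosine error between predicted
and reported directions with an L1 penalty on the weights,

    (1/N) sum_i (1 - cos(Th_hat_i - Th_i)) + alpha (|a_ret| + |a_eye|),

with (a_ret, a_eye) constrained to [0, 1] via a logistic reparameterization
and optimized by multi-start Nelder-Mead; alpha is chosen by k-fold
cross-validated cosine error.  Binary depth reports are fit with a
cumulative-Gaussian psychometric function with lapses by maximum
likelihood; its slope is the derivative of the fitted function at its
midpoint.  Smooth-pursuit gain is estimated from eye traces by
derivative-of-Gaussian filtering, saccade removal by velocity/acceleration
thresholds, a pointwise median across traces, and a peak-velocity ratio
against the pursuit target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import VelocityProfile, direction_to_velocity, velocity_to_direction

__all__ = [
    "TRIAL_COLUMNS",
    "EyeTrace",
    "PsychometricParams",
    "ObserverFit",
    "fit_linear_observer",
    "fit_psychometric",
    "psychometric_function",
    "compute_pursuit_gain",
    "fixation_check",
    "fold_and_pool",
    "group_stats",
    "hodges_lehmann",
    "participant_permutation_test",
    "NoPursuitDataError",
    "UnderdeterminedFitError",
]

TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "geometry",
    "eye_condition",
    "eye_dir",
    "retinal_dir_deg",
    "retinal_speed_deg_s",
    "eye_speed_deg_s",
    "report_dir_deg",
    "depth_report",
    "valid",
]

# standardized width constant of the psychometric function:
# the stimulus span between the 5% and 95% points of the underlying Gaussian
PSYCH_C = float(stats.norm.ppf(0.95) - stats.norm.ppf(0.05))


class NoPursuitDataError(RuntimeError):
    """Every sample of every trace was removed by the artifact thresholds."""


class UnderdeterminedFitError(ValueError):
    """The trial design cannot constrain the observer weights."""


@dataclass
class EyeTrace:
    """Gaze and target position time series for one trial."""

    time: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    target_x: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.gaze_x) == len(self.gaze_y) == len(self.target_x) == n):
            raise ValueError("EyeTrace series must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


# --------------------------------------------------------------------------
# Observer-weight fitting (mean cosine error + L1)
# --------------------------------------------------------------------------

def _sigmoid(z):
    from scipy.special import expit

    return expit(z)


def _logit(p):
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(p / (1.0 - p))


def _predicted_directions(ret_x, ret_y, eye_x, a_ret, a_eye):
    vx = (1.0 - a_ret) * ret_x + a_eye * eye_x
    return velocity_to_direction(vx, ret_y)


def _cosine_error(theta_hat_deg, theta_deg):
    return float(np.mean(1.0 - np.cos(np.deg2rad(theta_hat_deg - theta_deg))))


def _trial_arrays(trials: pd.DataFrame, g_pursuit: float | None):
    """Slip-corrected (ret_x, ret_y, eye_x, report) arrays from a trial table."""
    t = trials[trials["valid"].astype(bool)].copy()
    t = t[t["report_dir_deg"].notna()]
    if len(t) == 0:
        raise UnderdeterminedFitError("no valid direction-report trials")
    vel = direction_to_velocity(
        t["retinal_dir_deg"].to_numpy(float), t["retinal_speed_deg_s"].to_numpy(float)
    )
    ret_x, ret_y = vel[:, 0], vel[:, 1]
    eye_x = t["eye_dir"].to_numpy(float) * t["eye_speed_deg_s"].to_numpy(float)
    if g_pursuit is not None:
        pursuit = (t["eye_condition"] == "Pursuit").to_numpy()
        ret_x = np.where(pursuit, ret_x + (1.0 - g_pursuit) * eye_x, ret_x)
        eye_x = np.where(pursuit, g_pursuit * eye_x, eye_x)
    reports = t["report_dir_deg"].to_numpy(float)
    return ret_x, ret_y, eye_x, reports


def _fit_weights_fixed_alpha(ret_x, ret_y, eye_x, reports, alpha, seed, n_starts=4):
    """Multi-start Nelder-Mead in logit space; returns (a_ret, a_eye, loss)."""
    rng = np.random.default_rng(seed)

    def objective(z):
        a_ret, a_eye = _sigmoid(z)
        theta_hat = _predicted_directions(ret_x, ret_y, eye_x, a_ret, a_eye)
        return _cosine_error(theta_hat, reports) + alpha * (abs(a_ret) + abs(a_eye))

    starts = [np.array([_logit(0.05), _logit(0.05)])]
    for _ in range(n_starts - 1):
        starts.append(_logit(rng.uniform(0.05, 0.95, size=2)))
    best = None
    for z0 in starts:
        res = optimize.minimize(
            objective, z0, method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-9}
        )
        if best is None or res.fun < best.fun:
            best = res
    a_ret, a_eye = _sigmoid(best.x)
    return float(a_ret), float(a_eye), float(best.fun)


@dataclass
class ObserverFit:
    """Result of the linear observer fit."""

    a_ret: float
    a_eye: float
    alpha_selected: float
    loss: float
    a_ret_ci: tuple[float, float] | None = None
    a_eye_ci: tuple[float, float] | None = None
    bootstrap_samples: np.ndarray | None = field(default=None, repr=False)


def fit_linear_observer(
    trials: pd.DataFrame,
    g_pursuit: float | None = None,
    alpha_grid=None,
    cv_folds: int = 5,
    bootstrap_n: int = 500,
    seed: int | None = None,
    n_starts: int = 4,
) -> ObserverFit:
    """Fit (a_ret, a_eye) to direction reports of one participant/condition.

    Parameters
    ----------
    trials : DataFrame
        Trial table rows of a single condition.  Needs >= 2 distinct retinal
        directions and both eye-direction signs.
    g_pursuit : float, optional
        Measured pursuit gain; when given, Pursuit trials are slip-corrected
        before fitting.
    alpha_grid : sequence, optional
        L1 strengths to cross-validate over; default 8 log-spaced points in
        [1e-4, 1].  Pass a single-element grid to skip cross-validation.
    bootstrap_n : int
        Trial resamples for the percentile CIs (0 disables bootstrapping).
    """
    ret_x, ret_y, eye_x, reports = _trial_arrays(trials, g_pursuit)
    dirs = trials.loc[trials["valid"].astype(bool), "retinal_dir_deg"]
    if dirs.nunique() < 2:
        raise UnderdeterminedFitError("need >= 2 distinct retinal directions")
    if np.unique(np.sign(eye_x[eye_x != 0])).size < 2:
        raise UnderdeterminedFitError("need both eye-direction signs")
    if alpha_grid is None:
        alpha_grid = np.logspace(-4, 0, 8)
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, dtype=float))
    rng = np.random.default_rng(seed)
    n = len(reports)

    if len(alpha_grid) == 1:
        alpha_sel = float(alpha_grid[0])
    else:
        folds = rng.permutation(n) % cv_folds
        cv_err = np.zeros(len(alpha_grid))
        for ai, alpha in enumerate(alpha_grid):
            for k in range(cv_folds):
                tr, te = folds != k, folds == k
                a_ret, a_eye, _ = _fit_weights_fixed_alpha(
                    ret_x[tr], ret_y[tr], eye_x[tr], reports[tr], alpha,
                    seed=rng.integers(2**31), n_starts=n_starts,
                )
                theta_hat = _predicted_directions(ret_x[te], ret_y[te], eye_x[te], a_ret, a_eye)
                cv_err[ai] += _cosine_error(theta_hat, reports[te])
        alpha_sel = float(alpha_grid[int(np.argmin(cv_err))])

    a_ret, a_eye, loss = _fit_weights_fixed_alpha(
        ret_x, ret_y, eye_x, reports, alpha_sel, seed=rng.integers(2**31),
        n_starts=n_starts,
    )

    a_ret_ci = a_eye_ci = None
    boots = None
    if bootstrap_n:
        boots = np.empty((bootstrap_n, 2))
        for b in range(bootstrap_n):
            idx = rng.integers(0, n, size=n)
            boots[b] = _fit_weights_fixed_alpha(
                ret_x[idx], ret_y[idx], eye_x[idx], reports[idx], alpha_sel,
                seed=rng.integers(2**31), n_starts=2,
            )[:2]
        a_ret_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        a_eye_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    return ObserverFit(a_ret, a_eye, alpha_sel, loss, a_ret_ci, a_eye_ci, boots)


# --------------------------------------------------------------------------
# Psychometric fitting (cumulative Gaussian with lapses, MLE)
# --------------------------------------------------------------------------

@dataclass
class PsychometricParams:
    """Cumulative-Gaussian psychometric parameters and derived slope."""

    mean_m: float
    width_w: float
    lapse_lambda: float
    guess_gamma: float
    slope: float
    nll: float = math.nan
    boundary_flag: bool = False
    ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_w <= 0 and not self.boundary_flag:
            raise ValueError("width_w must be positive")


def psychometric_function(x, m, w, lapse=0.0, guess=0.0):
    """P(far) at stimulus level x: guess + (1 - lapse - guess) * Phi(C (x-m)/w)."""
    x = np.asarray(x, dtype=float)
    return guess + (1.0 - lapse - guess) * stats.norm.cdf(PSYCH_C * (x - m) / w)


def _psych_slope(w, lapse, guess):
    # d/dx at x = m: (1 - lapse - guess) * C/w * phi(0)
    return (1.0 - lapse - guess) * PSYCH_C / (w * math.sqrt(2.0 * math.pi))


def fit_psychometric(
    directions,
    responses,
    bootstrap_n: int = 0,
    seed: int | None = None,
    lapse_max: float = 0.1,
    width_bounds: tuple[float, float] = (1.0, 1000.0),
) -> PsychometricParams:
    """Maximum-likelihood cumulative-Gaussian fit to binary far/near reports.

    ``responses`` are coded far = 1.  Requires >= 3 distinct stimulus
    levels.  When every response is identical the fit is degenerate: a
    boundary fit is flagged and the slope reported as 0 with a warning.
    Bootstrap CIs (``bootstrap_n`` > 0) resample trials within each level.
    """
    x = np.asarray(directions, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("directions and responses must align")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 stimulus levels")
    if np.all(y == y[0]):
        warnings.warn("all responses identical: boundary psychometric fit", stacklevel=2)
        return PsychometricParams(
            mean_m=math.nan, width_w=math.nan, lapse_lambda=0.0,
            guess_gamma=0.0, slope=0.0, boundary_flag=True,
        )

    span = x.max() - x.min()

    # an ascending function cannot capture far-rates that fall with x: allow
    # fitting both orientations and keeping the better likelihood
    best = None
    for flip in (False, True):
        yy = 1.0 - y if flip else y

        def nll_o(params, yy=yy):
            m, w, lam, gam = params
            p = np.clip(psychometric_function(x, m, w, lam, gam), 1e-9, 1 - 1e-9)
            return -np.sum(yy * np.log(p) + (1.0 - yy) * np.log(1.0 - p))

        x0 = np.array([float(np.median(x)), max(span / 2.0, 5.0), 0.02, 0.02])
        res = optimize.minimize(
            nll_o, x0, method="L-BFGS-B",
            bounds=[(x.min() - span, x.max() + span), width_bounds,
                    (0.0, lapse_max), (0.0, lapse_max)],
        )
        if best is None or res.fun < best[0].fun:
            best = (res, flip)
    res, flip = best
    m, w, lam, gam = res.x
    slope = _psych_slope(w, lam, gam) * (-1.0 if flip else 1.0)
    out = PsychometricParams(m, w, lam, gam, slope, nll=float(res.fun))

    if bootstrap_n:
        rng = np.random.default_rng(seed)
        levels = np.unique(x)
        samples = {"mean_m": [], "width_w": [], "slope": []}
        for _ in range(bootstrap_n):
            xb, yb = [], []
            for lv in levels:
                yi = y[x == lv]
                yb.append(rng.choice(yi, size=len(yi), replace=True))
                xb.append(np.full(len(yi), lv))
            fb = fit_psychometric(
                np.concatenate(xb), np.concatenate(yb), bootstrap_n=0,
                lapse_max=lapse_max, width_bounds=width_bounds,
            )
            samples["mean_m"].append(fb.mean_m)
            samples["width_w"].append(fb.width_w)
            samples["slope"].append(fb.slope)
        for k, v in samples.items():
            v = np.asarray(v, dtype=float)
            v = v[np.isfinite(v)]
            if len(v):
                out.ci[k] = tuple(np.percentile(v, [2.5, 97.5]))
    return out


# --------------------------------------------------------------------------
# Eye-trace processing
# --------------------------------------------------------------------------

def _dog_kernel(sample_rate: float, sd_s: float = 0.025) -> np.ndarray:
    """First-derivative-of-Gaussian differentiator (units: 1/s).

    Convolving position (deg) with this kernel yields velocity (deg/s):
    the kernel is the analytic derivative of a unit-area Gaussian, sampled
    and scaled by the sample interval.
    """
    half = int(round(4.0 * sd_s * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    g = np.exp(-0.5 * (t / sd_s) ** 2) / (sd_s * math.sqrt(2.0 * math.pi))
    dg = -t / sd_s**2 * g
    # position is convolved against a time-reversed kernel; with the odd
    # kernel this flips sign, so negate here such that increasing position
    # gives positive velocity
    return -dg / sample_rate


def trace_velocity(trace: EyeTrace, sd_s: float = 0.025) -> np.ndarray:
    """Horizontal gaze velocity (deg/s) by derivative-of-Gaussian filtering."""
    kernel = _dog_kernel(trace.sample_rate, sd_s)
    pad = len(kernel) // 2
    padded = np.pad(trace.gaze_x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def compute_pursuit_gain(
    traces: list[EyeTrace],
    target_profile: VelocityProfile,
    velocity_threshold: float = 40.0,
    acceleration_threshold: float = 300.0,
    filter_sd_s: float = 0.025,
) -> float:
    """Pursuit gain: peak of the median filtered eye velocity over the target peak.

    Per trace: velocity by derivative-of-Gaussian filtering (SD 25 ms);
    samples with |velocity| > 40 deg/s or |acceleration| > 300 deg/s^2
    (catch-up saccades and artifacts) are dropped, not interpolated.  The
    pointwise median across traces then gives a single velocity profile
    whose peak is compared against the target's peak speed.  The target
    peak is measured through the same differentiating filter so that the
    filter's slight peak attenuation cancels in the ratio (an eye trace
    identical to the target scores exactly 1).
    """
    if not traces:
        raise ValueError("need at least one trace")
    n = min(len(tr.gaze_x) for tr in traces)
    stack = np.full((len(traces), n), np.nan)
    for i, tr in enumerate(traces):
        v = trace_velocity(tr, filter_sd_s)[:n]
        a = np.gradient(v, 1.0 / tr.sample_rate)
        bad = (np.abs(v) > velocity_threshold) | (np.abs(a) > acceleration_threshold)
        v = v.copy()
        v[bad] = np.nan
        stack[i] = v
    if np.all(np.isnan(stack)):
        raise NoPursuitDataError("all samples removed by artifact thresholds")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(stack, axis=0)
    peak = np.nanmax(np.abs(median))
    target_trace = EyeTrace(
        time=np.arange(len(target_profile.velocity_samples)) / target_profile.sample_rate,
        gaze_x=target_profile.position(),
        gaze_y=np.zeros_like(target_profile.velocity_samples),
        target_x=target_profile.position(),
        sample_rate=target_profile.sample_rate,
    )
    target_peak = float(np.max(np.abs(trace_velocity(target_trace, filter_sd_s))))
    if target_peak == 0:
        raise ValueError("target profile has zero peak speed")
    return float(peak / target_peak)


def fixation_check(
    trace: EyeTrace,
    window_half_width: float = 5.0,
    max_violation_ms: float = 100.0,
) -> bool:
    """True iff gaze never leaves the window around the target for too long.

    The window is a rectangle of half-width ``window_half_width`` (deg)
    centered on the (possibly moving) target; excursions shorter than
    ``max_violation_ms`` are tolerated.
    """
    out_x = np.abs(trace.gaze_x - trace.target_x) > window_half_width
    out_y = np.abs(trace.gaze_y) > window_half_width
    outside = out_x | out_y
    if not np.any(outside):
        return True
    max_run = 0
    run = 0
    for o in outside:
        run = run + 1 if o else 0
        max_run = max(max_run, run)
    return (max_run / trace.sample_rate) * 1000.0 <= max_violation_ms


# --------------------------------------------------------------------------
# Pooling / folding for visualization
# --------------------------------------------------------------------------

def _wrap_direction(d):
    """Wrap direction(s) into [-90, 270)."""
    return (np.asarray(d, dtype=float) + 90.0) % 360.0 - 90.0


def fold_and_pool(trials: pd.DataFrame) -> pd.DataFrame:
    """Fold direction-report trials for visualization (never for fitting).

    Directions in (90, 270) are reflected about the horizontal axis
    (stimulus and report alike), then rightward-eye trials are mirrored
    about the vertical axis into the leftward-eye frame.  Folding an
    already-folded table is a no-op.
    """
    t = trials.copy()
    d = _wrap_direction(t["retinal_dir_deg"])
    r = _wrap_direction(t["report_dir_deg"])

    lower = (d > 90.0) & (d < 270.0)
    d = np.where(lower, 180.0 - d, d)
    r = np.where(lower, 180.0 - r, r)

    right = t["eye_dir"].to_numpy(float) > 0
    d = np.where(right, -d, d)
    r = np.where(right, -r, r)
    t["retinal_dir_deg"] = _wrap_direction(d)
    t["report_dir_deg"] = _wrap_direction(r)
    t["eye_dir"] = np.where(right, -t["eye_dir"], t["eye_dir"])
    return t


# --------------------------------------------------------------------------
# Group statistics
# --------------------------------------------------------------------------

def hodges_lehmann(diffs, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Hodges-Lehmann estimate (median of Walsh averages) with its CI.

    The distribution-free CI comes from the signed-rank distribution: the
    (k+1)-th smallest and k-th largest Walsh averages bound the interval,
    with k the lower critical value of the Wilcoxon signed-rank statistic.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    i, j = np.triu_indices(n)
    walsh = np.sort((d[i] + d[j]) / 2.0)
    est = float(np.median(walsh))
    m = len(walsh)
    # normal approximation to the signed-rank critical value
    z = stats.norm.ppf(0.5 + ci / 2.0)
    mean_w = n * (n + 1) / 4.0
    sd_w = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    k = int(math.floor(mean_w - z * sd_w))
    k = max(k, 0)
    lo = walsh[k] if k < m else walsh[0]
    hi = walsh[m - 1 - k] if k < m else walsh[-1]
    return est, (float(lo), float(hi))


def group_stats(values_a, values_b, ci: float = 0.95) -> dict:
    """Paired two-sided Wilcoxon signed-rank summary (a - b).

    Returns Z (normal approximation), p, the Hodges-Lehmann estimate of the
    paired difference with a distribution-free CI, and the effect size
    r_W = Z / sqrt(n).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must align")
    n = len(a)
    if n < 5:
        raise ValueError("need n >= 5 pairs")
    d = a - b
    if np.all(d == 0):
        hl, hl_ci = hodges_lehmann(d, ci)
        return {
            "wilcoxon_Z": 0.0,
            "p": 1.0,
            "hodges_lehmann_estimate": hl,
            "CI": hl_ci,
            "effect_r": 0.0,
            "n": n,
        }
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
    # signed Z recovered from the (tie-corrected) two-sided p-value, with the
    # sign taken from the rank sum of positive differences (positive: a > b)
    dz = d[d != 0]
    ranks = stats.rankdata(np.abs(dz))
    w_plus = float(np.sum(ranks[dz > 0]))
    mean_w = len(dz) * (len(dz) + 1) / 4.0
    z_mag = float(stats.norm.isf(min(res.pvalue, 1.0) / 2.0))
    z = z_mag if w_plus > mean_w else (-z_mag if w_plus < mean_w else 0.0)
    hl, hl_ci = hodges_lehmann(d, ci)
    return {
        "wilcoxon_Z": float(z),
        "p": float(res.pvalue),
        "hodges_lehmann_estimate": hl,
        "CI": hl_ci,
        "effect_r": float(z / math.sqrt(n)),
        "n": n,
    }


def participant_permutation_test(
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation test on |psychometric slope| between two conditions.

    The null is built by shuffling the condition labels across the pooled
    trials and refitting the psychometric slope in each pseudo-condition;
    the two-sided p-value is for the observed |slope_a| - |slope_b|.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)

    def slope_of(df):
        d = df[df["valid"].astype(bool) & df["depth_report"].notna()]
        x = d["retinal_dir_deg"].to_numpy(float)
        y = (d["depth_report"] == "far").to_numpy(float)
        try:
            return fit_psychometric(x, y).slope
        except ValueError:
            return 0.0

    obs = abs(slope_of(trials_a)) - abs(slope_of(trials_b))
    pooled = pd.concat([trials_a, trials_b], ignore_index=True)
    n_a = len(trials_a)
    null = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.permutation(len(pooled))
        pa = pooled.iloc[idx[:n_a]]
        pb = pooled.iloc[idx[n_a:]]
        null[k] = abs(slope_of(pa)) - abs(slope_of(pb))
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    return float(p)
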