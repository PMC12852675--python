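"""Parametric joint retinal x eye velocity tuning model for MT-like neurons.

Firing rate over signed horizontal velocities::

    rate = A [ g(v_eye) f(v_retina + w v_eye) + o(v_eye) ]+  +  B

    g(v) = 2 / (1 + exp(-alpha v))                      multiplicative gain
    f(v) = exp(-(log((|v|+delta)/(s+delta)))^2 / (2 sigma^2))
           * exp(kappa (cos(Theta(v) - phi) - 1))       log-Gaussian speed x
                                                        von Mises direction
    o(v) = 2 / (1 + exp(-beta v)) - 1                   additive modulation

where [.]+ rectifies before scaling, Theta(v) maps the sign of a horizontal
velocity onto direction (+90 deg rightward for v > 0, -90 deg for v < 0),
and the shift weight w in [-1, 1] measures how far retinal-velocity tuning
is displaced by eye velocity: 0 is retina-centered, 1 world-centered.

Fitting assumes Poisson spike counts and minimizes the negative
log-likelihood with multi-start bounded optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MTModelParams",
    "firing_rate",
    "fit_poisson",
    "MTFitResult",
    "shift_distribution_compare",
    "DegenerateFitError",
]

_RIGHT = math.pi / 2.0  # direction of positive horizontal velocity, rad


class DegenerateFitError(RuntimeError):
    """All counts are zero: the rate model is unidentifiable."""


@dataclass
class MTModelParams:
    """The ten parameters of the joint-tuning rate model."""

    amplitude_A: float
    baseline_B: float
    shift_w: float
    gain_slope_alpha: float
    width_sigma: float
    offset_delta: float
    pref_speed_s: float
    direction_conc_kappa: float
    pref_direction_phi: float
    additive_slope_beta: float

    def __post_init__(self) -> None:
        if self.amplitude_A < 0 or self.baseline_B < 0:
            raise ValueError("amplitude and baseline must be nonnegative")
        if not (-1.0 <= self.shift_w <= 1.0):
            raise ValueError("shift_w must lie in [-1, 1]")
        if self.width_sigma <= 0 or self.offset_delta < 0 or self.pref_speed_s < 0:
            raise ValueError("invalid tuning-shape parameters")

    def as_array(self) -> np.ndarray:
        return np.array(list(asdict(self).values()))

    @classmethod
    def from_array(cls, arr) -> "MTModelParams":
        return cls(*[float(v) for v in arr])


def _gain(v, alpha):
    return 2.0 / (1.0 + np.exp(-alpha * v))


def _additive(v, beta):
    return 2.0 / (1.0 + np.exp(-beta * v)) - 1.0


def _tuning(v, sigma, delta, s, kappa, phi):
    speed = np.abs(v)
    logterm = np.log((speed + delta) / (s + delta))
    speed_part = np.exp(-0.5 * (logterm / sigma) ** 2)
    theta = np.where(np.asarray(v) >= 0, _RIGHT, -_RIGHT)
    dir_part = np.exp(kappa * (np.cos(theta - phi) - 1.0))
    return speed_part * dir_part


def firing_rate(v_retina, v_eye, params: MTModelParams):
    """Model firing rate (spikes/s) at signed velocities (deg/s)."""
    v_retina = np.asarray(v_retina, dtype=float)
    v_eye = np.asarray(v_eye, dtype=float)
    if not (np.all(np.isfinite(v_retina)) and np.all(np.isfinite(v_eye))):
        raise ValueError("velocities must be finite")
    p = params
    drive = _gain(v_eye, p.gain_slope_alpha) * _tuning(
        v_retina + p.shift_w * v_eye,
        p.width_sigma, p.offset_delta, p.pref_speed_s,
        p.direction_conc_kappa, p.pref_direction_phi,
    ) + _additive(v_eye, p.additive_slope_beta)
    return p.amplitude_A * np.maximum(drive, 0.0) + p.baseline_B


@dataclass
class MTFitResult:
    """Best-fit parameters with the final NLL and convergence diagnostics."""

    params: MTModelParams
    nll: float
    n_starts: int
    n_converged: int


# bounds keep f, g, o numerically stable
_BOUNDS = [
    (0.0, 500.0),   # A
    (0.0, 100.0),   # B
    (-1.0, 1.0),    # w
    (-1.0, 1.0),    # alpha
    (0.05, 5.0),    # sigma
    (0.01, 10.0),   # delta
    (0.0, 30.0),    # s
    (0.0, 10.0),    # kappa
    (-math.pi, math.pi),  # phi
    (-1.0, 1.0),    # beta
]


def fit_poisson(
    counts: pd.DataFrame,
    starts: int = 10,
    seed: int | None = None,
    count_window_s: float = 1.0,
) -> MTFitResult:
    """Poisson maximum-likelihood fit of the rate model to a count table.

    ``counts`` has columns v_retina, v_eye, trial, count.  Counts are
    pooled per grid cell (a Poisson sum), so the cell likelihood uses rate
    ``n_trials * count_window_s * lambda``.
    """
    for col in ("v_retina", "v_eye", "count"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    pooled = counts.groupby(["v_retina", "v_eye"], as_index=False).agg(
        total=("count", "sum"), n=("count", "size")
    )
    if counts["v_retina"].nunique() < 5 or counts["v_eye"].nunique() < 5:
        raise ValueError("grid must cover >= 5 levels on each axis")
    if (pooled["total"] == 0).all():
        raise DegenerateFitError("all spike counts are zero")
    vr = pooled["v_retina"].to_numpy(float)
    ve = pooled["v_eye"].to_numpy(float)
    k = pooled["total"].to_numpy(float)
    exposure = pooled["n"].to_numpy(float) * count_window_s

    def nll(x):
        lam = firing_rate(vr, ve, MTModelParams.from_array(x)) * exposure
        lam = np.maximum(lam, 1e-9)
        return float(np.sum(lam - k * np.log(lam)))

    rng = np.random.default_rng(seed)
    mean_rate = float(k.sum() / exposure.sum())
    best = None
    n_conv = 0
    for si in range(starts):
        if si == 0:
            x0 = np.array([
                max(mean_rate, 1.0), max(0.1 * mean_rate, 0.1), 0.0, 0.1,
                1.0, 0.5, 5.0, 1.0, _RIGHT, 0.0,
            ])
        else:
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in _BOUNDS])
            x0[0] = rng.uniform(0.5, 3.0) * max(mean_rate, 1.0)
            x0[1] = rng.uniform(0.0, max(0.5 * mean_rate, 1.0))
        x0 = np.clip(x0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=_BOUNDS)
        n_conv += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return MTFitResult(
        params=MTModelParams.from_array(best.x),
        nll=float(best.fun),
        n_starts=starts,
        n_converged=n_conv,
    )


def shift_distribution_compare(shifts_a, shifts_b) -> dict:
    """Rank-based comparison of two tuning-shift distributions.

    Two-sided Mann-Whitney U on independent samples; returns U, the
    normal-approximation Z, p, and the difference of medians (a - b).
    """
    a = np.asarray(shifts_a, dtype=float)
    b = np.asarray(shifts_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (res.statistic - mu) / sd
    return {
        "mann_whitney_U": float(res.statistic),
        "Z": float(z),
        "p": float(res.pvalue),
        "delta_median": float(np.median(a) - np.median(b)),
        "n": (n1, n2),
    }
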