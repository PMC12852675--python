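"""Perceptual observer model: predicted object direction and depth.

The observer receives the (slip-corrected) retinal velocity of an object and
the horizontal eye velocity, and forms two percepts:

* perceived world-relative motion, a linear combination of retinal and eye
  velocities whose weights depend on the inferred viewing geometry::

      w_obj_x = (1 - a_ret) * w_ret_x + a_eye * w_eye_x,
      a_ret = g_ret * p',   a_eye = (1 - p') * g_eye

  with gains ``g_ret`` (the fraction of horizontal retinal motion parsed as
  motion parallax) and ``g_eye`` (the fraction of eye velocity accounted
  for) — conceptually analogous to a flow-parsing gain;

* perceived relative depth from the motion-pursuit ratio::

      d_hat' = (g_ret * w_ret_x) / (g_eye * w_eye_x)

  which is undefined (ambiguous) when the denominator vanishes — the pure
  rotation geometry, where optic flow carries no depth information.

Real pursuit is imperfect: with pursuit gain ``g_pursuit`` the executed eye
velocity is ``g_pursuit * w_eye`` and the residual target motion lands on
the retina as slip, so the intended velocities are corrected before either
percept is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import direction_to_velocity, velocity_to_direction

__all__ = [
    "GeometryCondition",
    "EyeCondition",
    "ObserverParams",
    "TrialStimulus",
    "AmbiguousDepthError",
    "UndefinedDirectionError",
    "slip_correct",
    "predict_world_motion",
    "predict_direction",
    "predict_depth",
    "prediction_curves",
]


class GeometryCondition(str, Enum):
    """Background optic-flow condition."""

    R = "R"
    RT = "RT"
    NONE = "none"


class EyeCondition(str, Enum):
    """Real pursuit versus simulated eye movement with stable fixation."""

    PURSUIT = "Pursuit"
    FIXATION = "Fixation"


@dataclass(frozen=True)
class ObserverParams:
    """Gains and derived weights of the linear observer.

    ``a_ret`` scales down the horizontal retinal component attributed to
    motion parallax; ``a_eye`` scales the eye velocity added back for the
    coordinate transformation.  When built from gains and a geometry via
    :meth:`from_gains`, ``a_ret = g_ret * p'`` and ``a_eye = (1 - p') *
    g_eye``.
    """

    g_ret: float = 1.0
    g_eye: float = 1.0
    a_ret: float = 0.0
    a_eye: float = 0.0
    g_pursuit: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_ret", "g_eye", "a_ret", "a_eye"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.g_pursuit < 0:
            raise ValueError("g_pursuit must be >= 0")

    @classmethod
    def from_gains(
        cls,
        g_ret: float,
        g_eye: float,
        pprime: float,
        g_pursuit: float = 1.0,
    ) -> "ObserverParams":
        return cls(
            g_ret=g_ret,
            g_eye=g_eye,
            a_ret=g_ret * pprime,
            a_eye=(1.0 - pprime) * g_eye,
            g_pursuit=g_pursuit,
        )


@dataclass(frozen=True)
class TrialStimulus:
    """Intended stimulus velocities and condition labels of one trial."""

    retinal_velocity: tuple[float, float]
    eye_velocity_x: float
    geometry_condition: GeometryCondition = GeometryCondition.RT
    eye_condition: EyeCondition = EyeCondition.FIXATION


class AmbiguousDepthError(ValueError):
    """Depth percept is undefined (zero effective eye velocity)."""


class UndefinedDirectionError(ValueError):
    """Direction of a zero-length predicted velocity is undefined."""


def slip_correct(
    stimulus: TrialStimulus, g_pursuit: float
) -> tuple[float, np.ndarray]:
    """Correct intended velocities for imperfect pursuit.

    Only Pursuit trials are corrected: the executed eye velocity is
    ``g_pursuit * w_eye`` and the uncompensated remainder
    ``(1 - g_pursuit) * w_eye`` appears as retinal slip added to the
    horizontal retinal component.  Fixation trials (simulated eye movement)
    carry no slip and pass through unchanged.
    """
    if g_pursuit < 0:
        raise ValueError("g_pursuit must be >= 0")
    ret = np.asarray(stimulus.retinal_velocity, dtype=float)
    eye = float(stimulus.eye_velocity_x)
    if stimulus.eye_condition != EyeCondition.PURSUIT:
        return eye, ret
    corrected_eye = g_pursuit * eye
    corrected_ret = ret.copy()
    corrected_ret[0] = ret[0] + (1.0 - g_pursuit) * eye
    return corrected_eye, corrected_ret


def predict_world_motion(
    corrected_ret, corrected_eye_x: float, params: ObserverParams
) -> np.ndarray:
    """Perceived world velocity: the weighted retinal/eye combination.

    Horizontal: ``(1 - a_ret) * w_ret_x + a_eye * w_eye_x``; the vertical
    retinal component passes through (eye motion is horizontal).
    """
    ret = np.asarray(corrected_ret, dtype=float)
    out = ret.copy()
    out[..., 0] = (1.0 - params.a_ret) * ret[..., 0] + params.a_eye * corrected_eye_x
    return out


def predict_direction(
    corrected_ret, corrected_eye_x: float, params: ObserverParams
) -> float:
    """Perceived direction (deg; up = 0, clockwise-positive) of the percept."""
    v = predict_world_motion(corrected_ret, corrected_eye_x, params)
    if np.all(v == 0.0):
        raise UndefinedDirectionError("zero predicted velocity has no direction")
    return float(velocity_to_direction(v[..., 0], v[..., 1]))


def predict_depth(
    corrected_ret_x: float, corrected_eye_x: float, params: ObserverParams
) -> float:
    """Perceived relative depth d-hat' from the motion-pursuit ratio.

    Raises
    ------
    AmbiguousDepthError
        If ``g_eye * w_eye_x == 0``: the percept the pure-rotation geometry
        produces, where optic flow is depth-invariant.
    """
    denom = params.g_eye * corrected_eye_x
    if denom == 0.0:
        raise AmbiguousDepthError("depth is ambiguous without effective eye velocity")
    return (params.g_ret * corrected_ret_x) / denom


def prediction_curves(
    params: ObserverParams,
    geometry: GeometryCondition | str = GeometryCondition.RT,
    eye_speed: float = 5.3,
    retinal_speed: float = 2.67,
    directions=None,
    depth_noise_sigma: float = 0.3,
) -> pd.DataFrame:
    """Model direction/depth predictions over a sweep of retinal directions.

    Returns a tidy frame with one row per (direction, eye sign):
    ``direction_in``, ``eye_sign``, ``direction_out`` (NaN where undefined)
    and ``p_far`` — the probability of a "far" report under a cumulative-
    Gaussian link on the predicted depth with width ``depth_noise_sigma``
    (0.5 where depth is ambiguous).
    """
    from scipy.stats import norm

    geometry = GeometryCondition(geometry)
    if directions is None:
        directions = np.arange(-90.0, 271.0, 30.0)
    directions = np.asarray(directions, dtype=float)
    rows = []
    for eye_sign in (-1.0, 1.0):
        eye = eye_sign * eye_speed
        for th in directions:
            ret = direction_to_velocity(th, retinal_speed)
            try:
                d_out = predict_direction(ret, eye, params)
            except UndefinedDirectionError:
                d_out = math.nan
            if geometry == GeometryCondition.R:
                p_far = 0.5  # depth-invariant flow: no depth signal
            else:
                try:
                    dhat = predict_depth(ret[0], eye, params)
                    p_far = float(norm.cdf(dhat / depth_noise_sigma))
                except AmbiguousDepthError:
                    p_far = 0.5
            rows.append(
                {
                    "direction_in": th,
                    "eye_sign": eye_sign,
                    "direction_out": d_out,
                    "p_far": p_far,
                }
            )
    return pd.DataFrame(rows)
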