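"""Forward viewing-geometry model and optic-flow simulation.

The central idea: when an observer's eye both translates and rotates, the
optic flow field produced by the eye movement is a rotation of the scene
about a *pivot* located somewhere between the eye and the fixation point.
Writing the pivot distance normalized by viewing distance as ``p'`` (p' = 0:
pure eye rotation, "R"; p' = 1: lateral translation with compensatory
counter-rotation about the fixation point, "R+T"), the scene-relative
angular velocity of an object at normalized depth ``d'`` (d' = depth /
viewing distance; negative = nearer than fixation) obeys a single linear
relation between its retinal velocity and the eye's rotational velocity::

    w_obj = w_ret + (1 - (1 + d') p') * w_eye

At p' = 0 this is the classic coordinate transformation w_obj = w_ret +
w_eye (depth drops out: rotational flow is depth-invariant).  At p' = 1
with a stationary object it inverts to the motion-pursuit law
d' = w_ret / w_eye.

All angular velocities are in deg/s.  Screen x is rightward-positive,
y upward-positive.  Direction angles put "up" at 0 deg and increase
clockwise, so direction = atan2(v_x, v_y).  Eye velocity is horizontal
(rightward-positive) by convention; the linear relation applies to the
horizontal component only, since all real and simulated pursuit here is
horizontal.

The small-angle linear relation is the canonical equation engine; the
perspective-projection flow simulator in this module is a validation and
visualization layer on top of it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViewingGeometry",
    "SceneObject",
    "RetinalMotion",
    "FlowField",
    "VelocityProfile",
    "direction_to_velocity",
    "velocity_to_direction",
    "field_of_view",
    "object_world_motion",
    "depth_from_parallax",
    "retinal_from_world",
    "stationary_dot_flow",
    "equation_depth",
    "gaussian_velocity_profile",
    "simulate_flow_field",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewingGeometry:
    """Scene-relative eye trajectory parameterized by the flow rotation pivot.

    Parameters
    ----------
    viewing_distance_f : float
        Distance from the eye to the fixation plane, cm.
    pivot_p : float
        Distance from the rotation pivot of the flow field to the cyclopean
        eye, cm. 0 for pure rotation (R); equal to ``viewing_distance_f``
        for the fixation-pivot geometry (R+T).
    eye_rotation_omega_eye : float
        World-referenced horizontal eye rotation velocity, deg/s,
        rightward-positive.
    eye_translation_component_omegaT : float
        Part of the eye rotation compensating for eye translation, deg/s.
    pursuit_component_omegaP : float
        Part of the eye rotation tracking a moving target, deg/s.
    """

    viewing_distance_f: float
    pivot_p: float
    eye_rotation_omega_eye: float
    eye_translation_component_omegaT: float = 0.0
    pursuit_component_omegaP: float = 0.0

    def __post_init__(self) -> None:
        for name in ("viewing_distance_f", "pivot_p", "eye_rotation_omega_eye"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.viewing_distance_f <= 0:
            raise ValueError("viewing_distance_f must be positive")
        split = self.eye_translation_component_omegaT + self.pursuit_component_omegaP
        if split != 0.0 and not math.isclose(
            split, self.eye_rotation_omega_eye, rel_tol=1e-9, abs_tol=1e-9
        ):
            raise ValueError(
                "eye_rotation_omega_eye must equal "
                "eye_translation_component_omegaT + pursuit_component_omegaP"
            )

    @property
    def pivot_norm_pprime(self) -> float:
        """Pivot distance normalized by viewing distance (p' = p / f)."""
        return self.pivot_p / self.viewing_distance_f

    @classmethod
    def pure_rotation(
        cls, omega_eye: float, viewing_distance_f: float = 57.0
    ) -> "ViewingGeometry":
        """R geometry: stationary eye rotating in place (p' = 0)."""
        return cls(
            viewing_distance_f=viewing_distance_f,
            pivot_p=0.0,
            eye_rotation_omega_eye=omega_eye,
            eye_translation_component_omegaT=0.0,
            pursuit_component_omegaP=omega_eye,
        )

    @classmethod
    def rotation_translation(
        cls, omega_eye: float, viewing_distance_f: float = 57.0
    ) -> "ViewingGeometry":
        """R+T geometry: lateral translation + counter-rotation (p' = 1)."""
        return cls(
            viewing_distance_f=viewing_distance_f,
            pivot_p=viewing_distance_f,
            eye_rotation_omega_eye=omega_eye,
            eye_translation_component_omegaT=omega_eye,
            pursuit_component_omegaP=0.0,
        )

    @classmethod
    def from_pprime(
        cls, pprime: float, omega_eye: float, viewing_distance_f: float = 57.0
    ) -> "ViewingGeometry":
        """Intermediate geometry with an arbitrary normalized pivot."""
        return cls(
            viewing_distance_f=viewing_distance_f,
            pivot_p=pprime * viewing_distance_f,
            eye_rotation_omega_eye=omega_eye,
        )


@dataclass(frozen=True)
class SceneObject:
    """An object at signed depth ``depth_d`` (cm) relative to fixation."""

    depth_d: float
    viewing_distance_f: float = 57.0
    world_motion_omega_obj: tuple[float, float] = (0.0, 0.0)
    eccentricity: float = 0.0

    @property
    def depth_norm_dprime(self) -> float:
        """d' = d / f; < 0 near, > 0 far relative to the fixation plane."""
        return self.depth_d / self.viewing_distance_f


@dataclass(frozen=True)
class RetinalMotion:
    """Eye-referenced image velocity and its translation/pursuit components."""

    omega_ret: tuple[float, float]
    component_T: float = 0.0
    component_P: float = 0.0


@dataclass
class FlowField:
    """Sampled optic flow: dot positions (cm), image positions/velocities."""

    dot_positions: np.ndarray  # (n, 3) cm, camera-start frame
    image_positions: np.ndarray  # (n, 2) deg
    image_velocities: np.ndarray  # (n, 2) deg/s

    def __post_init__(self) -> None:
        n = len(self.dot_positions)
        if len(self.image_positions) != n or len(self.image_velocities) != n:
            raise ValueError("FlowField arrays must have equal length")

    def __len__(self) -> int:
        return len(self.dot_positions)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dot_id": np.arange(len(self)),
                "x_deg": self.image_positions[:, 0],
                "y_deg": self.image_positions[:, 1],
                "vx_deg_s": self.image_velocities[:, 0],
                "vy_deg_s": self.image_velocities[:, 1],
                "depth_cm": self.dot_positions[:, 2],
            }
        )


@dataclass
class VelocityProfile:
    """A sampled speed profile whose discrete integral is the displacement."""

    duration_T: float
    sample_rate: float
    displacement_D: float
    velocity_samples: np.ndarray = field(repr=False)
    time: np.ndarray = field(repr=False, default=None)

    @property
    def peak_speed(self) -> float:
        return float(np.max(np.abs(self.velocity_samples))) if len(self.velocity_samples) else 0.0

    @property
    def mean_speed(self) -> float:
        return abs(self.displacement_D) / self.duration_T

    def position(self) -> np.ndarray:
        """Cumulative displacement at each sample (trapezoid-free: left sum)."""
        dt = 1.0 / self.sample_rate
        return np.cumsum(self.velocity_samples) * dt


# --------------------------------------------------------------------------
# Conventions and small helpers
# --------------------------------------------------------------------------

def direction_to_velocity(direction_deg, speed):
    """Velocity vector for a direction in the up-is-0, clockwise-positive frame."""
    th = np.deg2rad(np.asarray(direction_deg, dtype=float))
    return np.stack([speed * np.sin(th), speed * np.cos(th)], axis=-1)


def velocity_to_direction(vx, vy):
    """Direction (deg, up = 0, clockwise-positive) of a velocity vector."""
    return np.rad2deg(np.arctan2(vx, vy))


def field_of_view(width_cm: float, height_cm: float, distance_cm: float) -> tuple[float, float]:
    """Horizontal and vertical field of view (deg) of a flat display."""
    h = 2.0 * math.degrees(math.atan(width_cm / 2.0 / distance_cm))
    v = 2.0 * math.degrees(math.atan(height_cm / 2.0 / distance_cm))
    return h, v


def _check_finite(*vals) -> None:
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError("inputs must be finite")


# --------------------------------------------------------------------------
# The equation engine
# --------------------------------------------------------------------------

def object_world_motion(omega_ret, omega_eye: float, dprime: float, pprime: float) -> np.ndarray:
    """Object velocity in world coordinates from retinal and eye velocities.

    Applies ``w_obj = w_ret + (1 - (1 + d') p') * w_eye`` to the horizontal
    component; the vertical component passes through unchanged (eye motion
    is horizontal by convention).

    Parameters
    ----------
    omega_ret : (2,) array-like
        Retinal velocity (vx, vy), deg/s.
    omega_eye : float
        Horizontal eye rotation velocity, deg/s (world-referenced).
    dprime, pprime : float
        Normalized object depth and flow-pivot location.
    """
    omega_ret = np.asarray(omega_ret, dtype=float)
    _check_finite(omega_ret, omega_eye, dprime, pprime)
    coeff = 1.0 - (1.0 + dprime) * pprime
    out = omega_ret.copy()
    out[..., 0] = omega_ret[..., 0] + coeff * omega_eye
    return out


def retinal_from_world(omega_obj, omega_eye: float, dprime: float, pprime: float) -> np.ndarray:
    """Inverse map: retinal velocity of an object with known world motion."""
    omega_obj = np.asarray(omega_obj, dtype=float)
    _check_finite(omega_obj, omega_eye, dprime, pprime)
    coeff = 1.0 - (1.0 + dprime) * pprime
    out = omega_obj.copy()
    out[..., 0] = omega_obj[..., 0] - coeff * omega_eye
    return out


class UndefinedDepthError(ValueError):
    """Depth is indeterminate without eye rotation (w_eye = 0)."""


def depth_from_parallax(omega_ret_x: float, omega_obj_x: float, omega_eye: float) -> float:
    """Normalized depth of an object from motion parallax (fixation-pivot case).

    ``d' = (w_ret - w_obj) / w_eye`` — the motion-pursuit law generalized to
    an object that itself moves in the world; with a stationary object it
    reduces to ``d' = w_ret / w_eye``.
    """
    _check_finite(omega_ret_x, omega_obj_x, omega_eye)
    if omega_eye == 0:
        raise UndefinedDepthError("depth from parallax is undefined at zero eye velocity")
    return (omega_ret_x - omega_obj_x) / omega_eye


def stationary_dot_flow(dprime, pprime, omega_eye):
    """Horizontal image velocity of a stationary scene dot.

    ``w_ret = -(1 - (1 + d') p') * w_eye``.  At p' = 0 this is -w_eye for
    every depth (rotational flow is depth-invariant); at p' = 1 it is
    d' * w_eye, so near (d' < 0) and far (d' > 0) dots move oppositely.
    """
    dprime = np.asarray(dprime, dtype=float)
    _check_finite(dprime, pprime, omega_eye)
    return -(1.0 - (1.0 + dprime) * pprime) * np.asarray(omega_eye, dtype=float)


def equation_depth(dot_positions: np.ndarray, viewing_distance_f: float) -> np.ndarray:
    """Equation-convention depth d' of simulated scene points.

    The linear flow relation is exact on the horizontal meridian when its
    depth variable is taken as ``d' = (f - rho) / rho`` with ``rho`` the
    point's horizontal-plane distance from the eye: substituting into
    :func:`stationary_dot_flow` reproduces the projected azimuthal flow of
    a rigid pivot rotation identically (off-meridian discrepancies are of
    order eccentricity squared).  Note the resulting axis runs opposite to
    metric depth — to first order ``d' = -(rho - f)/f`` — i.e., the
    equation set's depth axis points toward the observer.  Use this mapping
    when comparing simulator output against the linear engine.
    """
    pts = np.asarray(dot_positions, dtype=float)
    rho = np.hypot(pts[..., 0], pts[..., 2])
    return (viewing_distance_f - rho) / rho


# --------------------------------------------------------------------------
# Stimulus kinematics
# --------------------------------------------------------------------------

def gaussian_velocity_profile(
    displacement_D: float, duration_T: float, sample_rate: float = 60.0
) -> VelocityProfile:
    """Gaussian speed profile spanning +/-3 sigma over the motion duration.

    sigma = T/6, centered at T/2.  Samples are rescaled so the discrete
    time-integral equals ``displacement_D`` exactly, which compensates for
    the ~0.27% of mass lost by truncating the Gaussian at +/-3 sigma.
    """
    if duration_T <= 0:
        raise ValueError("duration_T must be positive")
    if sample_rate < 2.0 / duration_T:
        raise ValueError("sample_rate must be at least 2 / duration_T")
    n = int(round(duration_T * sample_rate))
    dt = 1.0 / sample_rate
    # sample midpoints so the profile is exactly symmetric: v(t) = v(T - t)
    t = (np.arange(n) + 0.5) * dt
    sigma = duration_T / 6.0
    v = np.exp(-0.5 * ((t - duration_T / 2.0) / sigma) ** 2)
    integral = np.sum(v) * dt
    if displacement_D == 0.0:
        v = np.zeros_like(v)
    else:
        v *= displacement_D / integral
    return VelocityProfile(
        duration_T=duration_T,
        sample_rate=sample_rate,
        displacement_D=displacement_D,
        velocity_samples=v,
        time=t,
    )


# --------------------------------------------------------------------------
# Perspective-projection flow simulator (validation / visualization layer)
# --------------------------------------------------------------------------

def _project(points: np.ndarray, cam_pos: np.ndarray, cam_yaw: float) -> np.ndarray:
    """Angular image coordinates (deg) of world points for a yawed camera.

    The camera looks along +z when yaw = 0; positive yaw rotates the gaze
    rightward (toward +x).
    """
    rel = points - cam_pos
    c, s = math.cos(cam_yaw), math.sin(cam_yaw)
    # world -> camera: inverse yaw rotation about the y axis
    xc = c * rel[:, 0] - s * rel[:, 2]
    zc = s * rel[:, 0] + c * rel[:, 2]
    yc = rel[:, 1]
    az = np.degrees(np.arctan2(xc, zc))
    el = np.degrees(np.arctan2(yc, np.hypot(xc, zc)))
    return np.stack([az, el], axis=1)


def simulate_flow_field(
    geometry: ViewingGeometry,
    n_dots: int = 200,
    depth_range: tuple[float, float] = (-20.0, 20.0),
    object_mask: tuple[tuple[float, float], float] | None = None,
    seed: int | None = None,
    field_deg: tuple[float, float] = (80.0, 50.0),
    dt: float = 1.0 / 60.0,
) -> FlowField:
    """Optic flow of a stationary dot cloud under the eye trajectory.

    Dots are placed uniformly in image angle over ``field_deg`` and
    uniformly in depth over ``depth_range`` (cm relative to the fixation
    plane).  Image velocities come from finite-differencing perspective
    projections across one time step of the rigid eye trajectory: the eye
    orbits the flow pivot by ``omega_eye * dt`` while its gaze rotates by
    the same angle.

    ``object_mask`` is ``((center_x_deg, center_y_deg), radius_deg)``; dots
    whose image position falls within 2x the radius of the center are
    removed to avoid local motion interactions with the object.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    f = geometry.viewing_distance_f
    lo, hi = min(depth_range), max(depth_range)
    if f + lo <= 0:
        raise ValueError("depth interval must exclude the eye plane")
    rng = np.random.default_rng(seed)

    az = rng.uniform(-field_deg[0] / 2.0, field_deg[0] / 2.0, n_dots)
    el = rng.uniform(-field_deg[1] / 2.0, field_deg[1] / 2.0, n_dots)
    depth = rng.uniform(lo, hi, n_dots)
    z = f + depth
    x = z * np.tan(np.radians(az))
    y = z * np.tan(np.radians(el)) / np.cos(np.radians(az))
    points = np.stack([x, y, z], axis=1)

    # Eye trajectory: rotation about the pivot (0, 0, p) with world-referenced
    # angular velocity omega_eye (deg/s, rightward gaze rotation positive).
    p = geometry.pivot_p
    omega = math.radians(geometry.eye_rotation_omega_eye)
    pivot = np.array([0.0, 0.0, p])
    eye0 = np.zeros(3)

    def cam_at(t: float) -> tuple[np.ndarray, float]:
        phi = omega * t
        c, s = math.cos(phi), math.sin(phi)
        rel = eye0 - pivot
        pos = pivot + np.array(
            [c * rel[0] + s * rel[2], rel[1], -s * rel[0] + c * rel[2]]
        )
        return pos, phi

    pos0, yaw0 = cam_at(0.0)
    pos1, yaw1 = cam_at(dt)
    img0 = _project(points, pos0, yaw0)
    img1 = _project(points, pos1, yaw1)
    vel = (img1 - img0) / dt

    keep = np.ones(n_dots, dtype=bool)
    if object_mask is not None:
        (cx, cy), radius = object_mask
        dist = np.hypot(img0[:, 0] - cx, img0[:, 1] - cy)
        keep &= dist > 2.0 * radius
    if not np.any(keep):
        warnings.warn("empty flow field after masking", stacklevel=2)
    return FlowField(
        dot_positions=points[keep],
        image_positions=img0[keep],
        image_velocities=vel[keep],
    )
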