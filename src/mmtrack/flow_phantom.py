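"""Tube-phantom flow simulator: the synthetic ground truth for tracking.

The phantom is a straight tube of inner diameter ``d_tube`` carrying laminar
Poiseuille flow, with an adjustable constriction (cosine-tapered diameter
reduction) and a terminal circular bend in the horizontal plane.  A dense
microsphere carried by the flow translates with the local fluid velocity
(optionally lagging it) and rotates at half the local shear rate:

    fluid speed at relative radius rho:  v(rho) = v0_local * (1 - rho^2)
    rotation frequency:                  f_rot  = v0_local * rho / (2 pi R_local)

where mass continuity scales the local centerline velocity as
``v0_local = v0 * (d_tube / d_local)^2``.  Eliminating rho in a straight
tube (lag = 1) gives the closed-form velocity-frequency relation

    v = v0 - (pi * f_rot * d_tube)^2 / v0 .

Geometry is parameterized by the arc-length coordinate ``x`` along the
centerline: the straight section spans ``[-straight_length/2,
+straight_length/2]`` along the x axis, followed by the bend of radius
``bend_radius`` turning through ``bend_angle`` in the x-y plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mmtrack.errors import GeometryError, InvalidArgumentError

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class MagneticSphere:
    """Hard-magnetic microsphere used as flow tracer."""

    diameter: float           # m
    moment_magnitude: float   # A m^2
    density: float = 7400.0   # kg/m^3 (NdFeB powder, ~7x the carrier fluid)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidArgumentError("sphere diameter must be positive")
        if self.moment_magnitude < 0:
            raise InvalidArgumentError("moment_magnitude must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def moment_from_diameter(diameter: float, ratio: float = 0.9) -> float:
    """Dipole moment (A m^2) from sphere diameter and a moment-to-volume
    ratio in pA m^2 per cubic micrometer (default 0.9, the empirical value
    for magnetized NdFeB microspheres)."""
    if diameter <= 0 and diameter != 0:
        raise InvalidArgumentError("diameter must be >= 0")
    volume_um3 = (np.pi / 6.0) * (diameter * 1e6) ** 3
    return ratio * volume_um3 * 1e-12


@dataclass
class PhantomGeometry:
    """Straight tube + cosine-tapered constriction + circular bend."""

    tube_diameter: float = 1.5e-3       # m
    straight_length: float = 0.16       # m
    constriction_center_x: float = 0.0  # m, arc-length coordinate
    constriction_length: float = 0.01   # m, fully-constricted span
    reduction: float = 0.0              # fraction of diameter removed, [0, 1)
    taper_length: float = 1e-3          # m, cosine ramp at each end
    bend_radius: float = 0.02           # m
    bend_angle: float = np.pi / 2       # rad

    def __post_init__(self) -> None:
        if self.tube_diameter <= 0:
            raise InvalidArgumentError("tube_diameter must be positive")
        if self.constriction_length <= 0:
            raise InvalidArgumentError("constriction_length must be positive")
        if not (0.0 <= self.reduction < 1.0):
            raise InvalidArgumentError("reduction must be in [0, 1)")
        if self.taper_length < 0:
            raise InvalidArgumentError("taper_length must be >= 0")

    @property
    def x_min(self) -> float:
        return -self.straight_length / 2.0

    @property
    def x_max(self) -> float:
        """Total arc length end (straight section plus bend arc)."""
        return self.straight_length / 2.0 + self.bend_radius * self.bend_angle

    @property
    def constricted_diameter(self) -> float:
        return self.tube_diameter * (1.0 - self.reduction)


@dataclass
class FlowField:
    """Poiseuille flow in the unconstricted tube.

    Centerline velocity, flow rate and tube radius are linked by
    ``v0 = 2 Q / (pi R^2)`` (parabolic profile: centerline = 2x mean); the
    constructor enforces this to 1e-9 relative.
    """

    centerline_velocity: float      # m/s
    kinematic_viscosity: float      # m^2/s
    flow_rate: float                # m^3/s
    tube_diameter: float = 1.5e-3   # m, for the consistency check

    def __post_init__(self) -> None:
        if min(self.centerline_velocity, self.kinematic_viscosity, self.flow_rate) <= 0:
            raise InvalidArgumentError("flow parameters must be positive")
        r = self.tube_diameter / 2.0
        v0 = 2.0 * self.flow_rate / (np.pi * r * r)
        if abs(v0 - self.centerline_velocity) > 1e-9 * abs(v0):
            raise InvalidArgumentError(
                f"inconsistent Poiseuille flow: v0={self.centerline_velocity} but "
                f"2Q/(pi R^2)={v0}"
            )

    @classmethod
    def from_flow_rate(cls, flow_rate: float, tube_diameter: float = 1.5e-3,
                       kinematic_viscosity: float = 2e-6) -> "FlowField":
        r = tube_diameter / 2.0
        v0 = 2.0 * flow_rate / (np.pi * r * r)
        return cls(v0, kinematic_viscosity, flow_rate, tube_diameter)

    @classmethod
    def from_centerline(cls, centerline_velocity: float, tube_diameter: float = 1.5e-3,
                        kinematic_viscosity: float = 2e-6) -> "FlowField":
        r = tube_diameter / 2.0
        q = centerline_velocity * np.pi * r * r / 2.0
        return cls(centerline_velocity, kinematic_viscosity, q, tube_diameter)


@dataclass
class TrajectoryState:
    """Ground-truth pose and kinematics of the sphere at one sample."""

    t: float
    position: np.ndarray           # (3,) m
    theta: float                   # rad
    phi: float                     # rad
    true_velocity: float           # m/s, along-path sphere speed
    true_rotation_frequency: float  # Hz
    local_diameter: float          # m

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)


def local_lumen(geometry: PhantomGeometry, x: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Lumen diameter, centerline point and unit tangent at arc length ``x``.

    The diameter is ``tube_diameter`` outside the constriction,
    ``tube_diameter * (1 - reduction)`` over the fully-constricted span, with
    a smooth cosine ramp over ``taper_length`` at each end.
    """
    g = geometry
    if not (g.x_min - 1e-12 <= x <= g.x_max + 1e-12):
        raise InvalidArgumentError(
            f"x={x} outside phantom arc length [{g.x_min}, {g.x_max}]"
        )
    # diameter profile (measured along arc length; the constriction lies in
    # the straight section)
    s = abs(x - g.constriction_center_x)
    half = g.constriction_length / 2.0
    if s <= half:
        frac = 1.0
    elif g.taper_length > 0 and s <= half + g.taper_length:
        frac = 0.5 * (1.0 + np.cos(np.pi * (s - half) / g.taper_length))
    else:
        frac = 0.0
    diameter = g.tube_diameter * (1.0 - g.reduction * frac)

    x_bend = g.straight_length / 2.0
    if x <= x_bend:
        point = np.array([x, 0.0, 0.0])
        tangent = np.array([1.0, 0.0, 0.0])
    else:
        a = (x - x_bend) / g.bend_radius  # turn angle, in the x-y plane
        point = np.array(
            [x_bend + g.bend_radius * np.sin(a),
             g.bend_radius * (1.0 - np.cos(a)),
             0.0]
        )
        tangent = np.array([np.cos(a), np.sin(a), 0.0])
    return diameter, point, tangent


def local_kinematics(
    geometry: PhantomGeometry,
    flow: FlowField,
    relative_radius: float,
    x: float,
    lag: float = 1.0,
) -> tuple[float, float]:
    """Sphere speed (m/s) and rotation frequency (Hz) at arc length ``x``.

    Mass continuity raises the local centerline velocity by
    ``(d_tube / d_local)^2``; the sphere translates at ``lag`` times the
    local fluid speed and spins at half the local shear rate over 2 pi.
    """
    if not (0.0 <= relative_radius < 1.0):
        raise InvalidArgumentError("relative_radius must be in [0, 1)")
    if not (0.0 < lag <= 1.0):
        raise InvalidArgumentError("lag must be in (0, 1]")
    d_local, _, _ = local_lumen(geometry, x)
    v0_local = flow.centerline_velocity * (geometry.tube_diameter / d_local) ** 2
    fluid_speed = v0_local * (1.0 - relative_radius**2)
    r_local = d_local / 2.0
    f_rot = v0_local * relative_radius / (2.0 * np.pi * r_local)
    return lag * fluid_speed, f_rot


def _cross_section_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (vertical-ish, horizontal) basis of the lumen cross-section.

    e_v points toward the bottom wall (gravity), projected perpendicular to
    the tangent; e_h completes the right-handed triad.
    """
    down = -_Z
    e_v = down - np.dot(down, tangent) * tangent
    n = np.linalg.norm(e_v)
    if n < 1e-12:  # vertical tangent: fall back to x
        e_v = np.array([1.0, 0.0, 0.0]) - tangent[0] * tangent
        n = np.linalg.norm(e_v)
    e_v = e_v / n
    e_h = np.cross(tangent, e_v)
    return e_v, e_h


def simulate_trajectory(
    geometry: PhantomGeometry,
    flow: FlowField,
    sphere: MagneticSphere,
    duration: float,
    sample_rate: float,
    lag: float = 1.0,
    initial_relative_radius: float = 0.5,
    initial_radial_azimuth: float = 0.0,
    bend_drift_rate: float = 5.0,
    oscillation: dict | None = None,
    start_x: float | None = None,
    initial_rotation_phase: float = 0.0,
    seed: int | None = None,
) -> list[TrajectoryState]:
    """Explicit time stepping of the sphere through the phantom.

    The sphere starts at arc length ``start_x`` (default: phantom inlet) on
    the streamline at ``initial_relative_radius``, offset toward azimuth
    ``initial_radial_azimuth`` (0 = bottom wall).  Position advances along
    the local tangent at the local sphere speed; the relative radius is
    preserved through the constriction (streamline contraction) and decays
    toward the axis at ``bend_drift_rate`` (1/s) inside the bend — a
    phenomenological stand-in for secondary (Dean) flow.  The moment rotates
    about the local vorticity direction at the local rotation frequency;
    (theta, phi) are the spherical angles of the rotating unit moment.

    ``oscillation``, if given, is ``{"amplitude_fraction": a, "harmonic": k}``
    and superimposes a kinematic radial displacement
    ``a * R_local * sin(k * delta)`` locked to the rotation phase delta —
    emulating the lateral oscillations seen in real traces.

    The walk stops early if the sphere reaches the end of the phantom.
    Identical inputs produce identical output (the simulation itself is
    deterministic; ``seed`` is carried into metadata by callers).
    """
    if sphere.diameter >= geometry.constricted_diameter:
        raise GeometryError(
            f"sphere diameter {sphere.diameter} does not fit the constricted "
            f"lumen {geometry.constricted_diameter}"
        )
    if duration <= 0 or sample_rate <= 0:
        raise InvalidArgumentError("duration and sample_rate must be positive")
    if not (0.0 <= initial_relative_radius < 1.0):
        raise InvalidArgumentError("initial_relative_radius must be in [0, 1)")

    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate))
    x = geometry.x_min if start_x is None else float(start_x)
    rr = float(initial_relative_radius)
    alpha = float(initial_radial_azimuth)
    delta = float(initial_rotation_phase)
    x_bend = geometry.straight_length / 2.0

    osc_amp = 0.0
    osc_harm = 1.0
    if oscillation is not None:
        osc_amp = float(oscillation["amplitude_fraction"])
        osc_harm = float(oscillation["harmonic"])

    states: list[TrajectoryState] = []
    for i in range(n):
        if x > geometry.x_max:
            break
        d_local, center, tangent = local_lumen(geometry, x)
        speed, f_rot = local_kinematics(geometry, flow, rr, x, lag=lag)
        e_v, e_h = _cross_section_frame(tangent)
        radial = np.cos(alpha) * e_v + np.sin(alpha) * e_h

        r_local = d_local / 2.0
        offset = rr * (r_local - sphere.radius)
        if osc_amp > 0.0:
            offset = offset + osc_amp * r_local * np.sin(osc_harm * delta)
            offset = float(np.clip(offset, -(r_local - sphere.radius),
                                   r_local - sphere.radius))
        position = center + offset * radial

        # moment rotates in the plane spanned by tangent and radial direction
        # (axis = local vorticity, perpendicular to both)
        u = np.cos(delta) * tangent + np.sin(delta) * radial
        theta = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
        phi = float(np.arctan2(u[1], u[0]) % (2.0 * np.pi))

        states.append(
            TrajectoryState(
                t=i * dt,
                position=position,
                theta=theta,
                phi=phi,
                true_velocity=speed,
                true_rotation_frequency=f_rot,
                local_diameter=d_local,
            )
        )

        x += speed * dt
        delta += 2.0 * np.pi * f_rot * dt
        if x > x_bend:  # inside the bend: drift toward the tube center
            rr *= np.exp(-bend_drift_rate * dt)
    return states


_TRAJ_COLS = ["t", "x", "y", "z", "theta", "phi", "v_true", "f_rot_true", "d_local"]


def write_trajectory(states: Sequence[TrajectoryState], path: str | Path,
                     config: dict | None = None, seed: int | None = None) -> None:
    """Trajectory CSV (SI units) plus JSON sidecar echoing config and seed."""
    path = Path(path)
    rows = [
        [s.t, *s.position, s.theta, s.phi, s.true_velocity,
         s.true_rotation_frequency, s.local_diameter]
        for s in states
    ]
    pd.DataFrame(rows, columns=_TRAJ_COLS).to_csv(path, index=False, float_format="%.9g")
    sidecar = {"config": config, "seed": seed, "n_states": len(states)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_trajectory(path: str | Path) -> list[TrajectoryState]:
    df = pd.read_csv(path)
    return [
        TrajectoryState(
            t=row.t,
            position=np.array([row.x, row.y, row.z]),
            theta=row.theta,
            phi=row.phi,
            true_velocity=row.v_true,
            true_rotation_frequency=row.f_rot_true,
            local_diameter=row.d_local,
        )
        for row in df.itertuples()
    ]
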