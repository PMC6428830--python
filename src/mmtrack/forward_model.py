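"""Magnetic point-dipole forward model and recording synthesis.

A microsphere with permanent moment **m** at location r' produces, at a
sensor at r measuring along unit normal n, the flux density

    B = (mu0 / 4 pi) * [ 3 (n . u)(u . m) / |d|^3  -  (n . m) / |d|^3 ]

with d = r - r' and u = d/|d|.  The moment orientation is parameterized by
the polar angle theta (against z) and azimuth phi (in the x-y plane), so the
source has five degrees of freedom once |m| is known.

Recordings are samples x channels matrices in tesla; the serialized dialect
stores femtotesla for readability (CSV + JSON sidecar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mmtrack.errors import InvalidArgumentError, SingularityError
from mmtrack.sensor_geometry import SensorArray

#: mu0 / 4 pi, exactly, in T m / A.
MU0_OVER_4PI = 1e-7

#: Distances below this (meters) count as sensor-source coincidence.
_SINGULAR_DIST = 1e-9

_TWO_PI = 2.0 * np.pi


@dataclass
class DipolePose:
    """Source location plus moment orientation (theta, phi) and magnitude."""

    location: np.ndarray  # (3,) m
    theta: float          # rad, polar angle against z, in [0, pi]
    phi: float            # rad, azimuth in x-y, in [0, 2 pi)
    moment_magnitude: float  # A m^2

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float).reshape(3)
        if self.moment_magnitude < 0:
            raise InvalidArgumentError("moment_magnitude must be >= 0")
        self.theta, self.phi = canonical_angles(self.theta, self.phi)

    @property
    def moment_vector(self) -> np.ndarray:
        return moment_from_angles(self.moment_magnitude, self.theta, self.phi)


def canonical_angles(theta: float, phi: float) -> tuple[float, float]:
    """Fold (theta, phi) into theta in [0, pi], phi in [0, 2 pi).

    Folding theta across 0 or pi shifts phi by pi so the moment direction is
    unchanged.
    """
    theta = float(theta) % _TWO_PI
    if theta > np.pi:
        theta = _TWO_PI - theta
        phi = phi + np.pi
    phi = float(phi) % _TWO_PI
    return theta, phi


def moment_from_angles(m: float, theta: float, phi: float) -> np.ndarray:
    """Moment vector from magnitude and spherical angles.

    Returns ``m * (sin t cos p, sin t sin p, cos t)``; the norm equals ``m``.
    """
    if m < 0:
        raise InvalidArgumentError("moment magnitude must be >= 0")
    st = np.sin(theta)
    return np.array([m * st * np.cos(phi), m * st * np.sin(phi), m * np.cos(theta)])


def dipole_gain(array: SensorArray | None, location: np.ndarray,
                positions: np.ndarray | None = None,
                normals: np.ndarray | None = None) -> np.ndarray:
    """(P, 3) gain matrix G with channel values ``B = G @ m``.

    The dipole field is linear in the moment vector; this factorization is
    reused by the multi-start localization scoring.  Either an ``array`` or
    explicit ``positions``/``normals`` may be given.
    """
    if positions is None or normals is None:
        positions = array.positions
        normals = array.normals
    location = np.asarray(location, dtype=float).reshape(3)
    d = positions - location                       # (P, 3)
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < _SINGULAR_DIST):
        raise SingularityError("sensor coincident with source location")
    u = d / dist[:, None]
    ndotu = np.einsum("ij,ij->i", normals, u)
    inv_d3 = MU0_OVER_4PI / dist**3
    return inv_d3[:, None] * (3.0 * ndotu[:, None] * u - normals)


def dipole_field(pose: DipolePose, array: SensorArray) -> np.ndarray:
    """Per-channel flux density (tesla) of a dipole at ``pose``."""
    return dipole_gain(array, pose.location) @ pose.moment_vector


@dataclass
class Recording:
    """Sampled multichannel flux-density matrix (tesla) with metadata."""

    sample_rate: float        # Hz
    t0: float                 # s
    values: np.ndarray        # (n_samples, n_channels), tesla
    array_ref: str            # name of the SensorArray the columns follow
    channel_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("values must be a samples x channels matrix")
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("recording contains non-finite values")
        if len(self.channel_ids) != self.values.shape[1]:
            raise InvalidArgumentError("channel_ids length must match value columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


def noise_sigma(noise_density: np.ndarray | float, sample_rate: float) -> np.ndarray | float:
    """Per-sample noise standard deviation for a white density over the
    Nyquist bandwidth: sigma = a * sqrt(f_s / 2)."""
    return noise_density * np.sqrt(sample_rate / 2.0)


def synthesize_recording(
    states: Sequence,
    sphere,
    array: SensorArray,
    sample_rate: float,
    seed: int | None = None,
    t0: float | None = None,
) -> Recording:
    """Forward-project a trajectory onto the array and add channel noise.

    ``states`` is a sequence of trajectory states (``position``, ``theta``,
    ``phi`` attributes; see :mod:`mmtrack.flow_phantom`); ``sphere`` supplies
    the fixed moment magnitude.  With ``seed`` set, i.i.d. Gaussian noise with
    per-channel sigma ``noise_density * sqrt(sample_rate / 2)`` is added; the
    same (states, seed) pair reproduces the recording bit-exactly.  With
    ``seed=None`` the recording is noiseless.
    """
    if len(states) == 0:
        raise InvalidArgumentError("states must be non-empty")
    positions = array.positions
    normals = array.normals
    m = sphere.moment_magnitude
    values = np.empty((len(states), len(array)))
    for i, st in enumerate(states):
        g = dipole_gain(None, st.position, positions=positions, normals=normals)
        values[i] = g @ moment_from_angles(m, st.theta, st.phi)
    if seed is not None:
        rng = np.random.default_rng(seed)
        sigma = noise_sigma(array.noise_densities, sample_rate)
        values = values + rng.standard_normal(values.shape) * sigma[None, :]
    if t0 is None:
        t0 = float(getattr(states[0], "t", 0.0))
    return Recording(
        sample_rate=float(sample_rate),
        t0=t0,
        values=values,
        array_ref=array.name,
        channel_ids=array.channel_ids,
        seed=seed,
    )


def write_recording(rec: Recording, path: str | Path, array_file: str | None = None) -> None:
    """Write the CSV (values in fT, 6 significant digits) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.values * 1e15, columns=rec.channel_ids)
    df.insert(0, "t", rec.times)
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = {
        "sample_rate_hz": rec.sample_rate,
        "t0_s": rec.t0,
        "array_ref": rec.array_ref,
        "array_file": array_file,
        "units": "fT",
        "seed": rec.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (values back in tesla)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    channel_ids = [c for c in df.columns if c != "t"]
    return Recording(
        sample_rate=float(meta["sample_rate_hz"]),
        t0=float(meta["t0_s"]),
        values=df[channel_ids].to_numpy() * 1e-15,
        array_ref=meta.get("array_ref") or "",
        channel_ids=channel_ids,
        seed=meta.get("seed"),
    )
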