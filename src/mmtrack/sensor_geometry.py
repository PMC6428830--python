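"""Magnetometer-array geometries: channels, planar generators, CSV I/O.

A *channel* is a point magnetometer measuring one flux-density component
along its unit normal; a *station* may carry one (axial) or three (triaxial)
channels.  The geometry CSV dialect is
``channel_id,x,y,z,nx,ny,nz,noise_density`` with SI units (m, T/sqrt(Hz)),
``#`` comment lines permitted.

Coordinate convention (used package-wide): right-handed, x along the main
flow direction, z vertical toward the sensor plane, origin on the tube axis
at the phantom center.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from mmtrack.errors import InvalidArgumentError, ParseError

_UNIT_TOL = 1e-9

#: Channel flux noise density of the reference SQUID system, tesla/sqrt(Hz).
DEFAULT_NOISE_DENSITY = 3e-15


@dataclass(frozen=True)
class SensorChannel:
    """One scalar magnetometer channel.

    Parameters
    ----------
    channel_id : str
        Unique identifier; becomes the column name in recordings.
    position : (3,) array_like
        Sensor location in meters.
    normal : (3,) array_like
        Unit measurement direction (the component of **B** reported).
    noise_density : float
        White noise density in tesla/sqrt(Hz).
    """

    channel_id: str
    position: np.ndarray
    normal: np.ndarray
    noise_density: float = DEFAULT_NOISE_DENSITY

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        nrm = np.asarray(self.normal, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "normal", nrm)
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError(
                f"channel {self.channel_id!r}: non-finite position {pos}"
            )
        if abs(np.linalg.norm(nrm) - 1.0) > _UNIT_TOL:
            raise InvalidArgumentError(
                f"channel {self.channel_id!r}: normal {nrm} is not unit length"
            )
        if not (np.isfinite(self.noise_density) and self.noise_density >= 0):
            raise InvalidArgumentError(
                f"channel {self.channel_id!r}: noise_density must be >= 0"
            )


@dataclass
class SensorArray:
    """Ordered collection of channels; the order fixes recording columns."""

    channels: Sequence[SensorChannel]
    name: str = "array"

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidArgumentError(f"duplicate channel ids: {dupes}")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def positions(self) -> np.ndarray:
        """(P, 3) channel positions in meters."""
        return np.array([c.position for c in self.channels], dtype=float)

    @property
    def normals(self) -> np.ndarray:
        """(P, 3) unit measurement normals."""
        return np.array([c.normal for c in self.channels], dtype=float)

    @property
    def noise_densities(self) -> np.ndarray:
        """(P,) noise densities in T/sqrt(Hz)."""
        return np.array([c.noise_density for c in self.channels], dtype=float)


_AXES = {"x": np.array([1.0, 0.0, 0.0]),
         "y": np.array([0.0, 1.0, 0.0]),
         "z": np.array([0.0, 0.0, 1.0])}


def make_planar_array(
    n_x: int,
    n_y: int,
    extent_x: float,
    extent_y: float,
    height: float,
    triaxial: bool = True,
    noise_density: float = DEFAULT_NOISE_DENSITY,
    name: str | None = None,
) -> SensorArray:
    """Regular grid of magnetometer stations on the plane ``z = height``.

    The grid of ``n_x * n_y`` stations spans ``extent_x`` by ``extent_y``
    centered on the origin.  Triaxial stations emit three channels with
    normals x-hat, y-hat, z-hat; axial stations a single z-hat channel.

    Returns an array with ``n_x * n_y * (3 if triaxial else 1)`` channels.
    """
    if n_x < 1 or n_y < 1:
        raise InvalidArgumentError("n_x and n_y must be >= 1")
    if extent_x <= 0 or extent_y <= 0:
        raise InvalidArgumentError("extents must be positive")
    xs = np.linspace(-extent_x / 2, extent_x / 2, n_x) if n_x > 1 else np.array([0.0])
    ys = np.linspace(-extent_y / 2, extent_y / 2, n_y) if n_y > 1 else np.array([0.0])
    axes = "xyz" if triaxial else "z"
    channels = []
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            pos = np.array([x, y, height])
            for ax in axes:
                channels.append(
                    SensorChannel(f"s{i:02d}{j:02d}_{ax}", pos, _AXES[ax], noise_density)
                )
    if name is None:
        name = f"planar_{n_x}x{n_y}{'_triaxial' if triaxial else '_axial'}"
    return SensorArray(channels, name=name)


_HEADER = ["channel_id", "x", "y", "z", "nx", "ny", "nz", "noise_density"]


def write_array(array: SensorArray, path: str | Path) -> None:
    """Write the geometry CSV dialect; round-trips bit-exact with read_array."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for ch in array.channels:
            writer.writerow(
                [ch.channel_id]
                + [repr(float(v)) for v in ch.position]
                + [repr(float(v)) for v in ch.normal]
                + [repr(float(ch.noise_density))]
            )


def read_array(path: str | Path, name: str | None = None) -> SensorArray:
    """Read a geometry CSV; malformed rows raise :class:`ParseError` naming the line."""
    path = Path(path)
    channels: list[SensorChannel] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = next(csv.reader([line]))
            if not header_seen:
                if [f.strip() for f in fields] != _HEADER:
                    raise ParseError(f"{path}:{lineno}: expected header {','.join(_HEADER)}")
                header_seen = True
                continue
            if len(fields) != len(_HEADER):
                raise ParseError(f"{path}:{lineno}: expected {len(_HEADER)} fields, got {len(fields)}")
            cid = fields[0]
            if cid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate channel id {cid!r}")
            try:
                nums = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            try:
                ch = SensorChannel(cid, nums[0:3], nums[3:6], nums[6])
            except InvalidArgumentError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            seen.add(cid)
            channels.append(ch)
    if not channels:
        raise ParseError(f"{path}: no channels")
    return SensorArray(channels, name=name or path.stem)
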