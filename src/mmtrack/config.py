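"""Run configuration: one TOML/JSON document is the single source of truth.

Sections mirror the physical setup: ``[phantom]`` (tube geometry),
``[flow]`` (Poiseuille flow), ``[sphere]`` (the tracer), ``[array]`` (the
magnetometer grid), ``[simulation]`` (sampling, seeding and kinematic
options), ``[tracking]`` and ``[analysis]``.  Defaults reproduce the
reference experiment: a 1.5 mm tube at 30 ml/min (centerline 0.57 m/s,
Re = 212), a 1 cm constriction, 750 Hz sampling, a 7x7 triaxial planar
array 3.5 cm above the tube with 3 fT/sqrt(Hz) channels, and a dense
34.6 um sphere with a 10 nA m^2 moment lagging the flow at 65%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from mmtrack.errors import ConfigError
from mmtrack.flow_phantom import FlowField, MagneticSphere, PhantomGeometry
from mmtrack.localization import TrackerConfig
from mmtrack.sensor_geometry import SensorArray, make_planar_array


def default_config() -> dict[str, Any]:
    """Nested dict of defaults (the reference experiment, 50% reduction)."""
    return {
        "phantom": {
            "tube_diameter": 1.5e-3,
            "straight_length": 0.16,
            "constriction_center_x": 0.0,
            "constriction_length": 0.01,
            "reduction": 0.5,
            "taper_length": 1e-3,
            "bend_radius": 0.02,
            "bend_angle": math.pi / 2,
        },
        "flow": {
            "flow_rate": 30e-6 / 60.0,        # 30 ml/min in m^3/s
            "kinematic_viscosity": 2e-6,      # 2 mm^2/s
        },
        "sphere": {
            "diameter": 34.6e-6,
            "moment_magnitude": 1e-8,         # 10 nA m^2
            "density": 7400.0,
        },
        "array": {
            "n_x": 7,
            "n_y": 7,
            "extent_x": 0.15,
            "extent_y": 0.20,
            "height": 0.035,
            "triaxial": True,
            "noise_density": 3e-15,
        },
        "simulation": {
            "sample_rate": 750.0,
            "duration": 0.6,
            "lag": 0.65,
            "initial_relative_radius": 0.5,
            "initial_radial_azimuth": 0.0,
            "bend_drift_rate": 5.0,
            "start_x": None,
            "oscillation": None,
            "seed": 0,
        },
        "tracking": {
            "v_max": 2.0,
            "max_iterations": 200,
            "multi_start_grid_spacing": 5e-3,
            "multi_start_directions": 26,
        },
        "analysis": {
            "smooth_width": 10,
            "window": 0.05,
            "rel_threshold": 0.15,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by a TOML/JSON file, overlaid by ``overrides``."""
    cfg = default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            if path.suffix.lower() == ".json":
                loaded = json.loads(path.read_text())
            else:
                import tomllib

                loaded = tomllib.loads(path.read_text())
        except (ValueError, OSError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a table of sections")
        unknown = set(loaded) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


@dataclass
class RunConfig:
    """Validated, object-level view of a configuration dict."""

    geometry: PhantomGeometry
    flow: FlowField
    sphere: MagneticSphere
    array: SensorArray
    simulation: dict[str, Any]
    tracker: TrackerConfig
    analysis: dict[str, Any]
    raw: dict[str, Any]

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "RunConfig":
        try:
            geometry = PhantomGeometry(**cfg["phantom"])
            flow = FlowField.from_flow_rate(
                cfg["flow"]["flow_rate"],
                tube_diameter=geometry.tube_diameter,
                kinematic_viscosity=cfg["flow"]["kinematic_viscosity"],
            )
            sphere = MagneticSphere(**cfg["sphere"])
            array = make_planar_array(**cfg["array"])
            sim = dict(cfg["simulation"])
            tracker = TrackerConfig(
                moment_magnitude=sphere.moment_magnitude,
                sample_rate=sim["sample_rate"],
                **cfg["tracking"],
            )
            analysis = dict(cfg["analysis"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        return cls(geometry, flow, sphere, array, sim, tracker, analysis, cfg)
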