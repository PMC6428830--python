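"""Per-sample inverse dipole localization with a velocity-confined search.

Each sample of a recording is explained by a single dipole with known moment
magnitude; its five free parameters (three position coordinates plus the two
moment angles) minimize the least-squares misfit

    Omega(r', theta, phi) = argmin || B_meas - B_sim(r', theta, phi) ||^2

via damped (Levenberg-Marquardt-type) least squares.  Tracking warm-starts
every sample at the previous fit and confines the position update to a box
of half-width ``v_max / f_s`` per coordinate — the maximum physically
plausible per-sample displacement.  The first sample (or any cold start) is
seeded by a multi-start sweep: a coarse position grid spanning the array's
field of view, scored analytically over a fixed set of moment directions
(the field is linear in the moment), with the best candidates refined.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from mmtrack.errors import InvalidArgumentError
from mmtrack.forward_model import (
    DipolePose,
    Recording,
    canonical_angles,
    dipole_gain,
    moment_from_angles,
    noise_sigma,
)
from mmtrack.sensor_geometry import SensorArray

logger = logging.getLogger(__name__)

_FT = 1e15  # residuals are scaled to femtotesla for optimizer conditioning


@dataclass
class TrackerConfig:
    """Settings of the constrained per-sample dipole fit."""

    moment_magnitude: float            # A m^2, held fixed during the fit
    v_max: float = 2.0                 # m/s, max sphere speed per axis
    sample_rate: float = 750.0         # Hz, sets the warm-start box width
    max_iterations: int = 200
    gradient_tolerance: float = 1e-10
    residual_tolerance: float = 1e-12
    multi_start_grid_spacing: float = 5e-3   # m
    multi_start_directions: int = 26
    multi_start_depth_range: tuple[float, float] = (0.01, 0.06)  # m below array
    multi_start_refine: int = 3        # candidates polished with full fits
    low_signal_chi2: float = 1.5
    low_signal_peak_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.moment_magnitude <= 0:
            raise InvalidArgumentError("moment_magnitude must be positive")
        if self.v_max <= 0 or self.sample_rate <= 0:
            raise InvalidArgumentError("v_max and sample_rate must be positive")
        if self.gradient_tolerance <= 0 or self.residual_tolerance <= 0:
            raise InvalidArgumentError("tolerances must be positive")

    @property
    def step_half_width(self) -> float:
        """Per-coordinate half-width of the confined search region (m)."""
        return self.v_max / self.sample_rate


@dataclass
class SampleFit:
    """Fitted pose and diagnostics for one sample."""

    t: float
    pose: DipolePose
    residual_norm: float        # tesla
    reduced_chi2: float
    converged: bool
    n_iterations: int
    low_signal: bool = False


def _cube_directions(n: int) -> np.ndarray:
    """Unit vectors toward the faces, edges and corners of a cube (26 max)."""
    dirs = [
        np.array(v, dtype=float)
        for v in itertools.product((-1, 0, 1), repeat=3)
        if any(v)
    ]
    dirs = np.array([d / np.linalg.norm(d) for d in dirs])
    return dirs[: max(1, min(n, len(dirs)))]


def _residual_factory(b_meas, positions, normals, m):
    def resid(p):
        g = dipole_gain(None, p[:3], positions=positions, normals=normals)
        return (g @ moment_from_angles(m, p[3], p[4]) - b_meas) * _FT
    return resid


def _refine(resid, p0, bounds, config):
    lower, upper = bounds
    # keep the start strictly inside the box for the trust-region solver
    p0 = np.clip(p0, lower + 1e-15, upper - 1e-15)
    return least_squares(
        resid,
        p0,
        bounds=(lower, upper),
        method="trf",
        x_scale=np.array([1e-3, 1e-3, 1e-3, 1.0, 1.0]),
        xtol=config.residual_tolerance,
        ftol=config.residual_tolerance,
        gtol=config.gradient_tolerance,
        max_nfev=config.max_iterations * 6,
    )


def _multi_start_candidates(b_meas, array, config):
    """Coarse grid x direction sweep; returns poses ordered by score."""
    pos = array.positions
    x0, x1 = pos[:, 0].min(), pos[:, 0].max()
    y0, y1 = pos[:, 1].min(), pos[:, 1].max()
    z_top = pos[:, 2].min()
    d0, d1 = config.multi_start_depth_range
    h = config.multi_start_grid_spacing
    xs = np.arange(x0, x1 + h / 2, h) if x1 > x0 else np.array([x0])
    ys = np.arange(y0, y1 + h / 2, h) if y1 > y0 else np.array([y0])
    zs = np.arange(z_top - d1, z_top - d0 + h / 2, h)
    dirs = _cube_directions(config.multi_start_directions)
    m = config.moment_magnitude

    best: list[tuple[float, int, np.ndarray, np.ndarray]] = []
    idx = 0
    for z in zs:
        for x in xs:
            for y in ys:
                g = dipole_gain(None, np.array([x, y, z]),
                                positions=array.positions, normals=array.normals)
                fields = (g @ dirs.T) * m          # (P, n_dirs)
                scores = np.sum((fields - b_meas[:, None]) ** 2, axis=0)
                k = int(np.argmin(scores))
                best.append((float(scores[k]), idx, np.array([x, y, z]), dirs[k]))
                idx += 1
    # deterministic tie-break: score, then insertion index
    best.sort(key=lambda t: (t[0], t[1]))
    return best


def localize_sample(
    b_meas: np.ndarray,
    array: SensorArray,
    config: TrackerConfig,
    init: DipolePose | None = None,
    search_box: tuple[np.ndarray, np.ndarray] | None = None,
    t: float = 0.0,
) -> SampleFit:
    """Fit one dipole pose to one sample of channel values (tesla).

    With ``init`` given, a single damped least-squares refinement from that
    pose; otherwise a multi-start grid over the array field of view seeds the
    refinement and the best refined minimum wins (ties broken by start
    order).  ``search_box`` (lower, upper position bounds) confines the
    position; the moment angles are optimized unconstrained and folded back
    into their canonical ranges afterwards.  Non-convergence is reported via
    ``converged=False``, never an exception.
    """
    b_meas = np.asarray(b_meas, dtype=float).reshape(-1)
    if b_meas.shape[0] != len(array):
        raise InvalidArgumentError(
            f"b_meas has {b_meas.shape[0]} values for {len(array)} channels"
        )
    if not np.all(np.isfinite(b_meas)):
        raise InvalidArgumentError("b_meas contains non-finite values")

    resid = _residual_factory(b_meas, array.positions, array.normals,
                              config.moment_magnitude)

    if search_box is not None:
        lo = np.concatenate([np.asarray(search_box[0], float), [-np.inf, -np.inf]])
        hi = np.concatenate([np.asarray(search_box[1], float), [np.inf, np.inf]])
    else:
        lo = np.full(5, -np.inf)
        hi = np.full(5, np.inf)

    if init is not None:
        starts = [np.array([*init.location, init.theta, init.phi])]
    else:
        cands = _multi_start_candidates(b_meas, array, config)
        starts = []
        for _, _, loc, d in cands[: max(1, config.multi_start_refine)]:
            th = float(np.arccos(np.clip(d[2], -1, 1)))
            ph = float(np.arctan2(d[1], d[0]) % (2 * np.pi))
            starts.append(np.array([*loc, th, ph]))

    best_res = None
    for p0 in starts:
        res = _refine(resid, p0, (lo, hi), config)
        if best_res is None or res.cost < best_res.cost - 1e-30:
            best_res = res

    p = best_res.x
    theta, phi = canonical_angles(p[3], p[4])
    pose = DipolePose(p[:3].copy(), theta, phi, config.moment_magnitude)
    residual_norm = float(np.linalg.norm(best_res.fun)) / _FT

    sigma = noise_sigma(array.noise_densities, config.sample_rate)
    dof = max(len(array) - 5, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((best_res.fun / _FT) ** 2 / sigma**2) / dof) \
            if np.all(sigma > 0) else float("nan")

    model_peak = float(np.max(np.abs(best_res.fun / _FT + b_meas)))
    low_signal = bool(
        np.isfinite(chi2)
        and chi2 < config.low_signal_chi2
        and model_peak < config.low_signal_peak_sigma * float(np.max(sigma))
    )
    converged = bool(best_res.status > 0)
    if not converged:
        logger.debug("sample t=%g: fit did not converge (status %s)", t, best_res.status)
    return SampleFit(
        t=t,
        pose=pose,
        residual_norm=residual_norm,
        reduced_chi2=chi2,
        converged=converged,
        n_iterations=int(best_res.nfev),
        low_signal=low_signal,
    )


def track(
    recording: Recording,
    array: SensorArray,
    config: TrackerConfig,
    init: DipolePose | None = None,
) -> list[SampleFit]:
    """Localize every sample of a recording with warm starts.

    Sample 0 is localized by multi-start (or from ``init``); each subsequent
    sample is warm-started at the previous pose with the position confined to
    a box of half-width ``v_max / sample_rate`` per coordinate, so consecutive
    fitted positions can never violate the physical velocity bound.
    """
    if recording.n_samples == 0:
        raise InvalidArgumentError("empty recording")
    if recording.values.shape[1] != len(array):
        raise InvalidArgumentError("recording columns do not match array channels")

    cfg = config
    if cfg.sample_rate != recording.sample_rate:
        # the confinement box must follow the data's sampling
        cfg = TrackerConfig(**{**cfg.__dict__, "sample_rate": recording.sample_rate})

    times = recording.times
    fits: list[SampleFit] = []
    first = localize_sample(recording.values[0], array, cfg, init=init, t=times[0])
    fits.append(first)
    half = cfg.step_half_width
    for i in range(1, recording.n_samples):
        prev = fits[-1].pose
        box = (prev.location - half, prev.location + half)
        fit = localize_sample(
            recording.values[i], array, cfg, init=prev, search_box=box, t=times[i]
        )
        fits.append(fit)
        if not fit.converged:
            logger.debug("sample %d (t=%g s) flagged non-converged", i, times[i])
    n_bad = sum(not f.converged for f in fits)
    logger.info("tracked %d samples, %d non-converged, %d low-signal",
                len(fits), n_bad, sum(f.low_signal for f in fits))
    return fits


_TRACK_COLS = ["t", "x", "y", "z", "theta", "phi", "residual_fT",
               "reduced_chi2", "converged", "flag"]


def write_track(fits: Sequence[SampleFit], path: str | Path,
                config: TrackerConfig | None = None) -> None:
    """Track CSV + JSON sidecar echoing the tracker configuration."""
    path = Path(path)
    rows = [
        [f.t, *f.pose.location, f.pose.theta, f.pose.phi,
         f.residual_norm * _FT, f.reduced_chi2, int(f.converged),
         "low_signal" if f.low_signal else ""]
        for f in fits
    ]
    pd.DataFrame(rows, columns=_TRACK_COLS).to_csv(path, index=False, float_format="%.9g")
    if config is not None:
        echo = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in config.__dict__.items()}
        path.with_suffix(".json").write_text(json.dumps({"tracker": echo}, indent=2))


def read_track(path: str | Path) -> pd.DataFrame:
    """Read a track CSV into a DataFrame (columns as written by write_track)."""
    return pd.read_csv(path)
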