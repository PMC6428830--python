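"""Velocity and rotational-frequency traces from a fitted track, the
theoretical velocity-frequency relation, and flow-event classification.

Velocity is the per-sample displacement norm times the sampling frequency
(v_i = |r'_i - r'_{i-1}| f_s), smoothed by a short centered moving average.
The rotation frequency is estimated in two steps: a prefit frequency f_pre
from the spectrogram of the moment-component traces (refined by the wrapped
phase rate between consecutive moment directions, which follows rapid
chirps), then a sliding-window sine fit whose window width adapts to
W = 2 f_s / f_pre samples (two expected periods).

Flow events are classified from windowed relative changes of the two traces:
a constriction raises both velocity and rotation frequency (continuity plus
increased shear) and is transient; a shear-zone shift toward the tube center
raises velocity but lowers the frequency; a shift toward the wall does the
opposite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares

from mmtrack.errors import InvalidArgumentError

_TWO_PI = 2.0 * np.pi


@dataclass
class KinematicsTrace:
    """Aligned per-sample kinematic estimates."""

    t: np.ndarray
    velocity: np.ndarray | None      # m/s (filled by the pipeline)
    rotation_frequency: np.ndarray   # Hz
    prefit_frequency: np.ndarray     # Hz
    window_samples: np.ndarray       # W used at each sample
    no_rotation: bool = False


@dataclass
class FlowEvent:
    """A classified interval of the passage."""

    kind: str                         # constriction | shift_to_center | shift_to_wall | steady | bend
    x_interval: tuple[float, float]   # m, along-track coordinate
    estimated_reduction: float | None
    score: float

    def __post_init__(self) -> None:
        if self.kind not in {"constriction", "shift_to_center", "shift_to_wall",
                             "steady", "bend"}:
            raise InvalidArgumentError(f"unknown event kind {self.kind!r}")
        if self.x_interval[0] > self.x_interval[1]:
            raise InvalidArgumentError("x_interval must be ordered")
        if self.estimated_reduction is not None and not (0 <= self.estimated_reduction < 1):
            raise InvalidArgumentError("estimated_reduction must be in [0, 1)")


def estimate_velocity(positions: np.ndarray, f_s: float, smooth_width: int = 10) -> np.ndarray:
    """Per-sample speed from positions: step norm times f_s, then a centered
    moving average of ``smooth_width`` samples (window shrinks at the edges).

    The step speed is assigned to the later sample; the first sample copies
    the second so the trace aligns with the positions.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 position samples")
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=1) * f_s
    v = np.concatenate([[steps[0]], steps])
    if smooth_width > 1:
        v = (
            pd.Series(v)
            .rolling(smooth_width, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return v


def _moment_components(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """(N, 3) unit moment directions from the angle traces."""
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _phase_rate(u: np.ndarray, f_s: float) -> np.ndarray:
    """Instantaneous |rotation rate| in Hz from the angle swept between
    consecutive moment directions (robust to axis drift and angle wrapping;
    a rotation faster than Nyquist folds, as it does for any sampled
    estimator)."""
    dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    crosses = np.linalg.norm(np.cross(u[:-1], u[1:]), axis=1)
    dphase = np.arctan2(crosses, dots)           # in [0, pi]
    f = dphase * f_s / _TWO_PI
    f = np.concatenate([[f[0]], f])
    if len(f) >= 5:
        f = signal.medfilt(f, kernel_size=5)
    return f


def _stft_prefit(traces: list[np.ndarray], f_s: float) -> float:
    """Dominant non-DC frequency of the summed spectrograms (coarse f_pre)."""
    n = len(traces[0])
    nperseg = int(min(256, max(16, 2 ** int(np.log2(max(n, 16))))))
    nperseg = min(nperseg, n)
    total = None
    for tr in traces:
        freqs, _, sxx = signal.spectrogram(
            tr - tr.mean(), fs=f_s, nperseg=nperseg,
            noverlap=nperseg // 2 if nperseg < n else 0,
        )
        p = sxx.sum(axis=1)
        total = p if total is None else total + p
    total[0] = 0.0  # drop DC
    return float(freqs[int(np.argmax(total))])


def _fit_sine(t: np.ndarray, y: np.ndarray, f0: float, f_s: float) -> tuple[float, float]:
    """Least-squares sine fit y ~ A sin(2 pi f t + p) + c seeded at f0.

    Returns (frequency, rms residual / data std).
    """
    y = y - y.mean()
    std = y.std()
    if std < 1e-12 or f0 <= 0:
        return 0.0, 0.0
    # seed amplitude/phase from quadrature correlation at f0
    s, c = np.sin(_TWO_PI * f0 * t), np.cos(_TWO_PI * f0 * t)
    a = 2 * np.mean(y * s)
    b = 2 * np.mean(y * c)
    p0 = np.array([np.hypot(a, b), f0, np.arctan2(b, a), 0.0])

    def resid(p):
        return p[0] * np.sin(_TWO_PI * p[1] * t + p[2]) + p[3] - y

    try:
        res = least_squares(
            resid, p0,
            bounds=([0.0, f0 * 0.25, -np.inf, -np.inf],
                    [np.inf, min(f0 * 4.0, f_s / 2), np.inf, np.inf]),
            method="trf", max_nfev=200,
        )
        rel = float(np.sqrt(np.mean(res.fun**2)) / std)
        return float(res.x[1]), rel
    except Exception:
        return f0, 1.0


def estimate_rotation_frequency(
    theta: np.ndarray, phi: np.ndarray, f_s: float
) -> KinematicsTrace:
    """Rotational-frequency trace from the orientation-angle traces.

    Works on the moment-direction components (cos(theta), sin(theta)cos(phi),
    ...) rather than the raw wrapped angles.  A prefit frequency trace f_pre
    — spectrogram dominant bin, refined by the wrapped phase rate so rapid
    chirps (e.g. a constriction burst) are followed — sets a per-window width
    W = 2 f_s / f_pre; each window gets a nonlinear sine fit seeded at
    f_pre, and the fitted frequencies are interpolated between window
    centers.  A non-rotating sphere yields an all-zero trace with the
    ``no_rotation`` flag set instead of an error.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = len(theta)
    if n < 4:
        raise InvalidArgumentError("need at least 4 samples")
    t = np.arange(n) / f_s
    u = _moment_components(theta, phi)
    comps = [u[:, 2], u[:, 0], u[:, 1]]  # cos(theta) first, then in-plane

    stds = [c.std() for c in comps]
    if max(stds) < 1e-3:
        zeros = np.zeros(n)
        return KinematicsTrace(t, None, zeros, zeros, np.zeros(n, dtype=int),
                               no_rotation=True)

    f_coarse = _stft_prefit([c for c, s in zip(comps, stds) if s > 1e-3], f_s)
    f_pre = _phase_rate(u, f_s)
    if f_coarse <= 0 and np.median(f_pre) < f_s / (2 * n):
        zeros = np.zeros(n)
        return KinematicsTrace(t, None, zeros, zeros, np.zeros(n, dtype=int),
                               no_rotation=True)
    f_pre = np.maximum(f_pre, f_s / (4.0 * n))  # at least a quarter cycle over the trace

    centers: list[int] = []
    fvals: list[float] = []
    wvals = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        # window width from the fastest prefit frequency within the baseline
        # lookahead, so short chirp bursts get windows matched to their scale
        w0 = int(np.clip(round(2.0 * f_s / float(f_pre[i])), 6, n))
        fp_win = float(np.max(f_pre[i:min(i + w0, n)]))
        w = int(np.clip(round(2.0 * f_s / fp_win), 6, n))
        j = min(i + w, n)
        if j - i < 4:
            break
        c = (i + j) // 2
        # fit the component with the most signal in this window
        seg_stds = [comp[i:j].std() for comp in comps]
        y = comps[int(np.argmax(seg_stds))][i:j]
        fp_local = float(f_pre[c])
        f_fit, rel = _fit_sine(t[i:j] - t[i], y, fp_local, f_s)
        if f_fit <= 0 or rel > 0.8:
            f_fit = fp_local  # poor sine fit: fall back to the phase-rate prefit
        centers.append(c)
        fvals.append(f_fit)
        wvals[i:j] = np.maximum(wvals[i:j], j - i)
        i += max(1, w // 2)

    f_rot = np.interp(np.arange(n), centers, fvals)
    return KinematicsTrace(t, None, np.maximum(f_rot, 0.0), f_pre, wvals)


def v_f_theory(f_rot: np.ndarray | float, v0: float, d_tube: float,
               scale: float = 1.0) -> np.ndarray | float:
    """Velocity-frequency relation of a sphere in quadratic (Poiseuille)
    flow: ``scale * (v0 - (pi f_rot d_tube)^2 / v0)``; may be negative for
    frequencies beyond the wall value (callers clip for plotting)."""
    if v0 <= 0:
        raise InvalidArgumentError("v0 must be positive")
    return scale * (v0 - (np.pi * np.asarray(f_rot, dtype=float) * d_tube) ** 2 / v0)


def reynolds(flow_rate: float, d_tube: float, kinematic_viscosity: float
             ) -> tuple[float, float]:
    """Mean velocity and Reynolds number of tube flow from the flow rate."""
    if min(flow_rate, d_tube, kinematic_viscosity) <= 0:
        raise InvalidArgumentError("all inputs must be positive")
    v_avg = flow_rate / (np.pi * d_tube**2 / 4.0)
    return v_avg, v_avg * d_tube / kinematic_viscosity


def estimate_reduction(v_baseline: float, v_constriction: float) -> float:
    """Diameter-reduction fraction from the velocity ratio via mass
    continuity (v scales with 1/d^2): ``1 - sqrt(v_base / v_constriction)``."""
    if v_baseline <= 0 or v_constriction < v_baseline:
        raise InvalidArgumentError("need v_constriction >= v_baseline > 0")
    return 1.0 - float(np.sqrt(v_baseline / v_constriction))


def classify_flow_events(
    velocity: np.ndarray,
    f_rot: np.ndarray,
    x: np.ndarray,
    f_s: float,
    window: float = 0.05,
    rel_threshold: float = 0.15,
    peak_velocity: np.ndarray | None = None,
) -> list[FlowEvent]:
    """Classify flow perturbations from aligned velocity/frequency traces.

    Windowed means (hop = half a window) are compared against the track
    baseline (the median windowed value).  Both traces up beyond
    ``rel_threshold`` marks a constriction — confirmed only if both return to
    baseline afterwards (a monotone rise instead indicates a progressively
    narrowing vessel); velocity up with frequency down marks a shear-zone
    shift toward the tube center; the mirrored pattern a shift toward the
    wall.  Adjacent same-kind windows merge into one event with its
    ``x_interval`` read off the x trace.

    ``peak_velocity`` (optional, e.g. the unsmoothed velocity) is used to
    estimate the diameter reduction of a constriction from the velocity peak
    inside the event: a short transit dilutes windowed means, while the peak
    preserves the continuity ratio.
    """
    velocity = np.asarray(velocity, dtype=float)
    f_rot = np.asarray(f_rot, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (len(velocity) == len(f_rot) == len(x)):
        raise InvalidArgumentError("traces must have equal length")
    n = len(velocity)
    if n < 2:
        raise InvalidArgumentError("traces too short")
    if peak_velocity is None:
        peak_velocity = velocity
    else:
        peak_velocity = np.asarray(peak_velocity, dtype=float)
        if len(peak_velocity) != n:
            raise InvalidArgumentError("peak_velocity length mismatch")

    w = max(2, int(round(window * f_s)))
    hop = max(1, w // 2)
    starts = list(range(0, max(n - w, 0) + 1, hop)) or [0]
    v_means = np.array([velocity[s:s + w].mean() for s in starts])
    f_means = np.array([f_rot[s:s + w].mean() for s in starts])

    v_base = float(np.median(v_means))
    f_base = float(np.median(f_means))
    dv = (v_means - v_base) / v_base if v_base > 0 else np.zeros_like(v_means)
    df = (f_means - f_base) / f_base if f_base > 0 else np.zeros_like(f_means)

    kinds = []
    for a, b in zip(dv, df):
        if a > rel_threshold and b > rel_threshold:
            kinds.append("constriction")
        elif a > rel_threshold and b < -rel_threshold:
            kinds.append("shift_to_center")
        elif a < -rel_threshold and b > rel_threshold:
            kinds.append("shift_to_wall")
        else:
            kinds.append("steady")

    # median-filtered peak trace for robust in-event velocity maxima
    pv = signal.medfilt(peak_velocity, kernel_size=3) if n >= 3 else peak_velocity

    events: list[FlowEvent] = []
    i = 0
    while i < len(kinds):
        j = i
        while j + 1 < len(kinds) and kinds[j + 1] == kinds[i]:
            j += 1
        kind = kinds[i]
        s0, s1 = starts[i], min(starts[j] + w, n) - 1
        score = float(np.max(np.minimum(np.abs(dv[i:j + 1]), np.abs(df[i:j + 1])))) \
            if kind != "steady" else 0.0
        reduction = None
        if kind == "constriction":
            returned = any(
                dv[k] < rel_threshold and df[k] < rel_threshold
                for k in range(j + 1, len(kinds))
            )
            if not returned:
                kind = "steady"
                score = 0.0
            else:
                v_peak = float(np.max(pv[s0:s1 + 1]))
                if v_peak > v_base:
                    reduction = estimate_reduction(v_base, v_peak)
                else:
                    reduction = 0.0
        lo, hi = sorted((float(x[s0]), float(x[s1])))
        events.append(FlowEvent(kind, (lo, hi), reduction, score))
        i = j + 1

    # merge adjacent events that collapsed to the same kind (e.g. demoted ones)
    merged: list[FlowEvent] = []
    for ev in events:
        if merged and merged[-1].kind == ev.kind:
            prev = merged[-1]
            merged[-1] = FlowEvent(
                ev.kind,
                (min(prev.x_interval[0], ev.x_interval[0]),
                 max(prev.x_interval[1], ev.x_interval[1])),
                prev.estimated_reduction or ev.estimated_reduction,
                max(prev.score, ev.score),
            )
        else:
            merged.append(ev)
    return merged
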