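"""Biphasic (triangle / half-sine) pulse parameterization of impact traces.

The competing simplified representation of a head impact replaces an
acceleration trace by a single idealized pulse described by two numbers:
a duration and a peak magnitude. The procedure is

1. locate the peak ``t_M`` at the maximum absolute acceleration;
2. scan outward from the peak for the initiation time ``t0`` (backward) and
   completion time ``t1`` (forward): each boundary sits at the first place
   where the trace's sign changes or its convexity (3-point central second
   difference) changes sign, whichever comes first;
3. integrate the trace over ``[t0, t1]`` (trapezoid rule) to get the
   velocity change ``delta_omega``;
4. convert the (``delta_omega``, ``dt``) pair into a pulse amplitude:
   ``2*delta_omega/dt`` for the triangle, ``(pi/2)*delta_omega/dt`` for the
   half-sine — both shapes conserve the area ``delta_omega`` exactly.

When the peak sits at (or within one sample of) the first or last sample,
``t0`` or ``t1`` cannot be defined and only half of the simplified pulse is
created; the one-sided interval is used as ``dt`` and the amplitude formulas
are applied unchanged (the half shapes below still conserve the area).

Boundary sample convention: a change is flagged between a pair of
consecutive samples; the boundary is the lower-index sample of the first
flagged pair. On the left this is the last pre-pulse sample, on the right
the last in-pulse sample, which makes the duration estimator unbiased for
pulses whose true boundaries fall between grid points. If no change occurs
before the record edge the boundary is clamped to the edge and the window
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from . import dataio
from .errors import ConfigError, NoPulseError

__all__ = [
    "PulseWindow",
    "BiphasicPulse",
    "detect_pulse",
    "fit_biphasic",
    "synthesize",
    "integrate_to_velocity",
    "fit_dataset",
    "build_biphasic_dataset",
]

_SHAPES = ("triangle", "half_sine")
# peak amplitude per unit (delta_omega / dt): triangle 2, half-sine pi/2
_SHAPE_FACTOR = {"triangle": 2.0, "half_sine": np.pi / 2.0}


@dataclass
class PulseWindow:
    """Detected pulse window on the sample grid (times in seconds)."""

    t_M: float
    alpha_M: float
    t0: float
    t1: float
    dt: float
    delta_omega: float
    half_pulse: str = "none"  # none | left_only | right_only
    clamped: bool = False
    i0: int = 0
    i_M: int = 0
    i1: int = 0

    def __post_init__(self) -> None:
        if self.half_pulse not in ("none", "left_only", "right_only"):
            raise ConfigError(f"bad half_pulse tag {self.half_pulse!r}")
        if self.dt <= 0:
            raise ConfigError("pulse window must have positive duration")
        if self.half_pulse == "none" and not (self.t0 <= self.t_M <= self.t1):
            raise ConfigError("window must bracket the peak (t0 <= t_M <= t1)")


@dataclass
class BiphasicPulse:
    """Fitted idealized pulse: shape tag, window, signed amplitude."""

    shape: str
    window: PulseWindow
    amplitude: float

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ConfigError(f"shape must be one of {_SHAPES}")
        if self.amplitude == 0.0:
            raise ConfigError("pulse amplitude must be nonzero")


def _second_difference(alpha: np.ndarray) -> np.ndarray:
    """3-point central second difference; edges padded with 0 (unused).

    Values below 1e-9 of the trace's peak are snapped to zero so that
    floating-point residue on straight segments (e.g. interpolated
    triangles) cannot masquerade as a convexity change.
    """
    d = np.zeros_like(alpha)
    d[1:-1] = alpha[:-2] - 2.0 * alpha[1:-1] + alpha[2:]
    d[np.abs(d) < 1e-9 * np.max(np.abs(alpha))] = 0.0
    return d


def _pair_changes(alpha: np.ndarray, d2: np.ndarray, j: int) -> bool:
    """True if a sign or convexity change is flagged between j and j+1.

    Zeros count as a sign change; convexity requires a strict flip of the
    second difference (and both stencil values to exist).
    """
    s0, s1 = np.sign(alpha[j]), np.sign(alpha[j + 1])
    if s0 != s1:
        return True
    m = alpha.shape[0]
    if 1 <= j and j + 1 <= m - 2 and d2[j] * d2[j + 1] < 0:
        return True
    return False


def detect_pulse(alpha_trace: np.ndarray, sample_rate: float) -> PulseWindow:
    """Locate the dominant pulse of an acceleration trace.

    Returns a :class:`PulseWindow`; raises :class:`NoPulseError` for an
    identically zero trace and :class:`ConfigError` for traces shorter than
    3 samples.
    """
    alpha = np.asarray(alpha_trace, dtype=float)
    if alpha.ndim != 1 or alpha.shape[0] < 3:
        raise ConfigError("trace must be 1-D with at least 3 samples")
    if not np.any(alpha):
        raise NoPulseError("all-zero trace has no pulse")
    m = alpha.shape[0]
    dt_s = 1.0 / sample_rate
    i_M = int(np.argmax(np.abs(alpha)))
    d2 = _second_difference(alpha)

    half = "none"
    if i_M <= 1:
        half = "right_only"
    elif i_M >= m - 2:
        half = "left_only"

    clamped = False
    # left boundary
    if half == "right_only":
        i0 = i_M
    else:
        i0 = None
        for j in range(i_M - 2, -1, -1):
            if _pair_changes(alpha, d2, j):
                i0 = j
                break
        if i0 is None:
            i0 = 0
            clamped = True
    # right boundary
    if half == "left_only":
        i1 = i_M
    else:
        i1 = None
        for j in range(i_M + 1, m - 1):
            if _pair_changes(alpha, d2, j):
                i1 = j
                break
        if i1 is None:
            i1 = m - 1
            clamped = True

    delta_omega = float(np.trapezoid(alpha[i0 : i1 + 1], dx=dt_s))
    return PulseWindow(
        t_M=i_M * dt_s,
        alpha_M=float(alpha[i_M]),
        t0=i0 * dt_s,
        t1=i1 * dt_s,
        dt=(i1 - i0) * dt_s,
        delta_omega=delta_omega,
        half_pulse=half,
        clamped=clamped,
        i0=i0,
        i_M=i_M,
        i1=i1,
    )


def fit_biphasic(window: PulseWindow, shape: str) -> BiphasicPulse:
    """Convert a detected window into a triangle or half-sine pulse.

    The amplitude magnitude comes from the area-preservation identities
    ``|amp| = 2|delta_omega|/dt`` (triangle) or ``(pi/2)|delta_omega|/dt``
    (half-sine); its sign is that of the measured peak.
    """
    if shape not in _SHAPES:
        raise ConfigError(f"shape must be one of {_SHAPES}")
    if window.dt <= 0:
        raise ConfigError("window duration must be positive")
    if window.delta_omega == 0.0:
        raise ConfigError("zero net velocity change: amplitude undefined")
    mag = _SHAPE_FACTOR[shape] * abs(window.delta_omega) / window.dt
    sign = 1.0 if window.alpha_M >= 0 else -1.0
    return BiphasicPulse(shape=shape, window=window, amplitude=sign * mag)


def synthesize(pulse: BiphasicPulse, time_grid: np.ndarray) -> np.ndarray:
    """Sample the idealized pulse on ``time_grid`` (zero outside support).

    Full pulses: the triangle rises linearly from 0 at ``t0`` to the
    amplitude at ``t_M`` and back to 0 at ``t1``; the half-sine is
    ``amp*sin(pi*(t-t0)/dt)``. Half pulses emit only the defined side as a
    ramp / quarter-wave, which still integrates to ``delta_omega``.
    """
    t = np.asarray(time_grid, dtype=float)
    w = pulse.window
    if t.shape[0] >= 2:
        step = float(np.median(np.diff(t)))
        if step > w.dt:
            raise ConfigError(
                f"time grid step {step:g}s is coarser than pulse "
                f"duration {w.dt:g}s"
            )
    if t[0] > w.t0 + 1e-12 or t[-1] < w.t1 - 1e-12:
        raise ConfigError("time grid does not cover the pulse window")
    amp = pulse.amplitude
    out = np.zeros_like(t)
    inside = (t >= w.t0 - 1e-12) & (t <= w.t1 + 1e-12)
    ti = t[inside]
    if pulse.shape == "triangle":
        if w.half_pulse == "none":
            out[inside] = np.interp(ti, [w.t0, w.t_M, w.t1], [0.0, amp, 0.0])
        elif w.half_pulse == "right_only":
            out[inside] = np.interp(ti, [w.t0, w.t1], [amp, 0.0])
        else:  # left_only
            out[inside] = np.interp(ti, [w.t0, w.t1], [0.0, amp])
    else:
        phase = (ti - w.t0) / w.dt
        if w.half_pulse == "none":
            out[inside] = amp * np.sin(np.pi * phase)
        elif w.half_pulse == "right_only":
            out[inside] = amp * np.cos(0.5 * np.pi * phase)
        else:  # left_only
            out[inside] = amp * np.sin(0.5 * np.pi * phase)
    return out


def integrate_to_velocity(
    alpha_trace: np.ndarray, sample_rate: float, omega0: float = 0.0
) -> np.ndarray:
    """Cumulative trapezoidal integral of acceleration, plus ``omega0``."""
    alpha = np.asarray(alpha_trace, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ConfigError("non-finite acceleration trace")
    return omega0 + cumulative_trapezoid(
        alpha, dx=1.0 / sample_rate, initial=0.0
    )


def fit_dataset(
    dataset: dataio.KinematicDataset,
    shape: str,
    qoi: str = "ang_acc",
) -> pd.DataFrame:
    """Fit one pulse per record and direction; return a tidy parameter table.

    ``qoi='ang_acc'`` fits the derived angular acceleration (the standard
    case); ``qoi='lin_acc'`` applies the same machinery to the linear
    channels.
    """
    if qoi not in ("ang_acc", "lin_acc"):
        raise ConfigError("fit qoi must be 'ang_acc' or 'lin_acc'")
    names = (
        dataio.ANGULAR_DIRECTIONS if qoi == "ang_acc" else dataio.LINEAR_DIRECTIONS
    )
    rows = []
    for rec in dataset:
        traces = (
            dataio.derive_angular_acceleration(rec)
            if qoi == "ang_acc"
            else rec.lin_acc
        )
        for d in range(3):
            try:
                w = detect_pulse(traces[d], rec.sample_rate)
                p = fit_biphasic(w, shape)
            except NoPulseError:
                continue
            rows.append(
                {
                    "record_id": rec.record_id,
                    "direction": names[d],
                    "t0": w.t0,
                    "tM": w.t_M,
                    "t1": w.t1,
                    "dt": w.dt,
                    "delta_omega": w.delta_omega,
                    "amplitude": p.amplitude,
                    "half_pulse": w.half_pulse,
                    "clamped": w.clamped,
                }
            )
    return pd.DataFrame(rows)


def build_biphasic_dataset(
    dataset: dataio.KinematicDataset, shape: str
) -> dataio.KinematicDataset:
    """Replace every channel of every record by its fitted idealized pulse.

    Angular channels: the derived angular acceleration is fitted, the pulse
    synthesized, and angular velocity recovered by direct temporal
    integration from rest (so it plateaus at ``delta_omega`` after the
    pulse). Linear channels are fitted and synthesized directly. Channels
    with no detectable pulse are zeroed.
    """
    records = []
    for rec in dataset:
        fs = rec.sample_rate
        t = rec.time
        ang_acc = dataio.derive_angular_acceleration(rec)
        ang_vel = np.zeros_like(rec.ang_vel)
        ang_acc_fit = np.zeros_like(rec.ang_vel)
        lin_acc = np.zeros_like(rec.lin_acc)
        for d in range(3):
            try:
                w = detect_pulse(ang_acc[d], fs)
                p = fit_biphasic(w, shape)
                ang_acc_fit[d] = synthesize(p, t)
                ang_vel[d] = integrate_to_velocity(ang_acc_fit[d], fs)
            except (NoPulseError, ConfigError):
                pass
            try:
                wl = detect_pulse(rec.lin_acc[d], fs)
                pl = fit_biphasic(wl, shape)
                lin_acc[d] = synthesize(pl, t)
            except (NoPulseError, ConfigError):
                pass
        records.append(
            dataio.KinematicRecord(
                record_id=rec.record_id,
                time=t.copy(),
                lin_acc=lin_acc,
                ang_vel=ang_vel,
                sample_rate=fs,
                ang_acc=ang_acc_fit,
            )
        )
    return dataio.KinematicDataset(
        records=records,
        provenance=f"{shape} biphasic fit of [{dataset.provenance}]",
        units=dict(dataset.units),
    )
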