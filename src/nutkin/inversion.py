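"""Estimators recovering the growth driver from observed kinematics.

Two inverse routes are provided:

* from the horizontal apical track ``(t, x_a, y_a)`` — the classical
  experimental measurement — under the whole-organ hypotheses (the organ
  bends in a single plane with uniform curvature): the direction of the
  smoothed tip velocity estimates ``psi_g(t)`` and the tip speed, scaled
  by ``2R/L^2``, estimates the drive ``Delta*Edot``;
* from full 3D curvature fields ``C(s, t)``, ``psi_c(s, t)`` sampled on
  material elements, inverting the curvature evolution law exactly:

      psi_g - psi_c = atan2(C R dpsi_c/dt, d(CR)/dt),
      Delta*Edot   = hypot(d(CR)/dt, C R dpsi_c/dt).

Derived periods: ``T_r = 2 pi / <dpsi_g/dt>`` (full rotation of the
growth direction) and ``T_o``, the mean time between alternate maxima of
``dpsi_g/dt`` (consecutive maxima sit ~pi apart in psi_g, so alternate
ones span a full turn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks, savgol_filter

from .geometry import ApicalTrack

__all__ = [
    "SmoothingSpec",
    "InversionResult",
    "NoSignalError",
    "estimate_psi_g_from_track",
    "estimate_delta_edot_from_track",
    "invert_from_3d",
    "rotation_period",
    "maxima_spacing",
    "curvature_from_tip",
    "invert_track",
    "default_window",
]


class NoSignalError(ValueError):
    """Raised when a track carries no usable kinematic signal."""


@dataclass(frozen=True)
class SmoothingSpec:
    """Savitzky-Golay smoothing/differentiation parameters.

    ``window`` is in samples (odd, > ``polyorder``); derivatives are the
    analytic derivatives of the local polynomial fit.  ``speed_floor``
    masks samples whose tip speed falls below this fraction of the
    track's median speed (the velocity direction is meaningless for a
    near-stationary tip).
    """

    window: int = 11
    polyorder: int = 3
    speed_floor: float = 0.01

    def __post_init__(self):
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and exceed polyorder")


@dataclass
class InversionResult:
    """Estimated driver history plus its derived periods."""

    times: np.ndarray
    psi_g_est: np.ndarray  # rad, unwrapped, NaN where masked
    delta_edot_est: np.ndarray  # 1/s (up to the 2R/L^2 prefactor assumption)
    mean_rate: float  # <dpsi_g/dt>, rad/s
    T_r: float  # s
    T_o: float | None = None  # s; None when no oscillation is detected


def default_window(track: ApicalTrack, fraction: float = 0.1) -> int:
    """Window (samples) covering ``fraction`` of the track's dominant period.

    The dominant period is located as the first positive-lag peak of the
    autocorrelation of the centered x signal; falls back to 1/10 of the
    track length when no peak exists.
    """
    x = track.x - track.x.mean()
    n = x.size
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    peaks, _ = find_peaks(acf)
    lag = int(peaks[0]) if peaks.size else n
    w = max(5, int(round(fraction * lag)))
    if w % 2 == 0:
        w += 1
    return min(w, n - 1 if (n - 1) % 2 else n - 2)


def _velocity(track: ApicalTrack, spec: SmoothingSpec):
    dt = np.diff(track.times)
    if track.times.size < 2 * spec.window:
        raise ValueError("track too short for the smoothing window")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("track must be uniformly sampled for smoothing")
    step = float(dt[0])
    vx = savgol_filter(track.x, spec.window, spec.polyorder, deriv=1, delta=step)
    vy = savgol_filter(track.y, spec.window, spec.polyorder, deriv=1, delta=step)
    return vx, vy


def estimate_psi_g_from_track(
    track: ApicalTrack,
    spec: SmoothingSpec | None = None,
    convention: str = "velocity",
) -> np.ndarray:
    """Principal growth direction from the direction of the tip velocity.

    Returns an unwrapped angle series aligned with ``track.times``; NaN
    where the speed falls below the floor or within one half-window of
    the ends (where the polynomial fit is one-sided).

    ``convention="velocity"`` (default) is the full-quadrant
    ``atan2(dy/dt, dx/dt)``; ``"printed"`` gives ``arctan(dx/dy)``, an
    angle referenced to the y axis and limited to a half turn — provided
    for comparison with legacy analyses.  A constant reference offset
    cancels in every derived rate and period.
    """
    spec = spec or SmoothingSpec()
    scale = max(np.ptp(track.x), np.ptp(track.y))
    if scale == 0:
        raise NoSignalError("tip is stationary: no direction signal")
    vx, vy = _velocity(track, spec)
    speed = np.hypot(vx, vy)
    floor = max(
        spec.speed_floor * np.median(speed),
        1e-9 * scale / np.diff(track.times).min(),  # numerical-noise floor
    )
    valid = speed > floor
    half = spec.window // 2
    valid[:half] = False
    valid[-half:] = False
    if valid.sum() < 2:
        raise NoSignalError("tip is (nearly) stationary: no direction signal")
    if valid.mean() < 0.9:
        raise NoSignalError(
            f"only {100 * valid.mean():.0f}% of samples exceed the speed floor"
        )
    psi = np.full(track.times.shape, np.nan)
    if convention == "velocity":
        psi[valid] = np.unwrap(np.arctan2(vy[valid], vx[valid]))
    elif convention == "printed":
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.arctan(vx[valid] / vy[valid])
        # arctan lives on a half turn: unwrap its pi-jumps
        psi[valid] = np.unwrap(raw, period=np.pi)
    else:
        raise ValueError("convention must be 'velocity' or 'printed'")
    return psi


def estimate_delta_edot_from_track(
    track: ApicalTrack,
    R: float,
    L: float,
    spec: SmoothingSpec | None = None,
) -> np.ndarray:
    """Differential-growth drive from the tip speed: ``(2R/L^2) |v|``.

    Under the uniform-plane-curvature hypotheses the tip radius is
    ``rho ~ C L^2 / 2``, so ``C*R = 2 R rho / L^2`` and the drive —
    the rate of the curvature vector — maps to the tip velocity scaled
    by ``2R/L^2``.  Strictly non-negative; NaN within one half-window of
    the track ends.
    """
    if R <= 0 or L <= 0:
        raise ValueError("R and L must be positive")
    spec = spec or SmoothingSpec()
    vx, vy = _velocity(track, spec)
    out = (2.0 * R / L**2) * np.hypot(vx, vy)
    half = spec.window // 2
    out[:half] = np.nan
    out[-half:] = np.nan
    return out


def invert_from_3d(
    C_field: np.ndarray,
    psi_c_field: np.ndarray,
    R: float,
    times: np.ndarray,
):
    """Exact inversion of the curvature evolution from Lagrangian fields.

    ``C_field`` and ``psi_c_field`` are (n_times, n_segments) arrays
    sampled on the *same material elements* across time.  Central
    differences of the curvature vector give its rate; the growth
    direction and drive follow exactly.  Returns ``(psi_g, delta_edot)``
    arrays of the same shape, NaN at the time endpoints and wherever
    both rate components vanish (degenerate, direction undefined).
    """
    C = np.asarray(C_field, dtype=float)
    psi = np.asarray(psi_c_field, dtype=float)
    t = np.asarray(times, dtype=float)
    if C.shape != psi.shape or C.shape[0] != t.size:
        raise ValueError("field shapes and times are inconsistent")
    kx = C * R * np.cos(psi)
    ky = C * R * np.sin(psi)
    kdx = np.gradient(kx, t, axis=0)
    kdy = np.gradient(ky, t, axis=0)
    delta_edot = np.hypot(kdx, kdy)
    psi_g = np.arctan2(kdy, kdx)
    degenerate = delta_edot == 0.0
    psi_g = np.where(degenerate, np.nan, psi_g)
    delta_edot = np.where(degenerate, np.nan, delta_edot)
    # one-sided endpoint differences are only first-order accurate: mask
    psi_g[0] = psi_g[-1] = np.nan
    delta_edot[0] = delta_edot[-1] = np.nan
    # unwrap each material element's series over its valid samples only
    for j in range(psi_g.shape[1]):
        col = psi_g[:, j]
        ok = np.isfinite(col)
        col[ok] = np.unwrap(col[ok])
    return psi_g, delta_edot


def rotation_period(psi_g_series: np.ndarray, times: np.ndarray):
    """Mean rotation rate of psi_g and the full-rotation period T_r.

    ``mean_rate`` is the total unwrapped change over the elapsed time
    between the first and last valid samples; ``T_r = 2 pi / mean_rate``.
    """
    psi = np.asarray(psi_g_series, dtype=float)
    t = np.asarray(times, dtype=float)
    valid = np.flatnonzero(np.isfinite(psi))
    if valid.size < 2:
        raise NoSignalError("need at least two valid psi_g samples")
    i, j = valid[0], valid[-1]
    mean_rate = (psi[j] - psi[i]) / (t[j] - t[i])
    if mean_rate == 0:
        raise NoSignalError("no net rotation of the growth direction")
    return mean_rate, 2.0 * np.pi / mean_rate


def maxima_spacing(
    rate_series: np.ndarray,
    times: np.ndarray,
    smooth_window: int | None = None,
    prominence_frac: float = 0.25,
) -> float:
    """Mean time between alternate maxima of a rate series (T_o).

    Consecutive maxima of ``dpsi_g/dt`` are expected ~pi apart in psi_g,
    so alternate maxima span a full rotation.  Raises
    :class:`NoSignalError` when fewer than three maxima are detected.
    """
    rate = np.asarray(rate_series, dtype=float)
    t = np.asarray(times, dtype=float)
    valid = np.isfinite(rate)
    rate, t = rate[valid], t[valid]
    if smooth_window and smooth_window >= 5:
        w = smooth_window + (smooth_window % 2 == 0)
        rate = savgol_filter(rate, int(w), 2)
    span = np.ptp(rate)
    if span == 0:
        raise NoSignalError("flat rate series: no maxima")
    peaks, _ = find_peaks(rate, prominence=prominence_frac * span)
    if peaks.size < 3:
        raise NoSignalError(f"only {peaks.size} maxima detected; need >= 3")
    tp = t[peaks]
    return float(np.mean(tp[2:] - tp[:-2]))


def curvature_from_tip(
    rho: float, theta: float, L: float, mode: str = "exact"
):
    """Whole-organ curvature and plane from one polar tip sample.

    Under the uniform-planar-curvature hypotheses the organ is a single
    arc of length L, so the horizontal tip radius is
    ``rho = (1 - cos(C L)) / C`` and the plane angle is ``psi_c = theta``.
    ``mode="exact"`` solves the arc relation numerically on its monotone
    branch; ``mode="small_curvature"`` uses the leading-order
    ``C = 2 rho / L^2``.  Returns ``(C, psi_c)``; ``psi_c`` is NaN at
    rho = 0 where the plane is undefined.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if rho == 0.0:
        return 0.0, np.nan
    if mode == "small_curvature":
        return 2.0 * rho / L**2, float(theta)
    if mode != "exact":
        raise ValueError("mode must be 'exact' or 'small_curvature'")
    # rho(u) = L (1 - cos u) / u is monotone for u in (0, u*], u* ~ 2.3311,
    # where u = C L; beyond it the tip has folded past the maximum reach
    u_star = brentq(lambda u: u * np.sin(u) - (1.0 - np.cos(u)), 2.0, np.pi)
    rho_max = L * (1.0 - np.cos(u_star)) / u_star

    def f(u):
        return L * (1.0 - np.cos(u)) / u - rho

    if rho > rho_max:
        raise ValueError(
            f"tip radius {rho:.4g} exceeds the reachable {rho_max:.4g} for "
            f"L = {L:.4g}: posture out of range"
        )
    lo = 1e-12
    if f(lo) > 0:  # rho below the linear regime floor: C -> 2 rho / L^2
        return 2.0 * rho / L**2, float(theta)
    u = brentq(f, lo, u_star, xtol=1e-14, rtol=1e-15)
    return u / L, float(theta)


def invert_track(
    track: ApicalTrack,
    R: float,
    L: float,
    spec: SmoothingSpec | None = None,
    convention: str = "velocity",
) -> InversionResult:
    """Full track inversion: psi_g(t), Delta*Edot(t), T_r and (if
    detectable) T_o."""
    spec = spec or SmoothingSpec(window=default_window(track))
    psi = estimate_psi_g_from_track(track, spec, convention=convention)
    dedot = estimate_delta_edot_from_track(track, R, L, spec)
    mean_rate, T_r = rotation_period(psi, track.times)
    rate = np.gradient(psi, track.times)
    try:
        # smooth over two windows: rate maxima live on the period scale
        T_o = maxima_spacing(rate, track.times, smooth_window=2 * spec.window + 1)
    except NoSignalError:
        T_o = None
    return InversionResult(track.times, psi, dedot, mean_rate, T_r, T_o)
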