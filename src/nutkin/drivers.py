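"""Endogenous-oscillator growth programs.

Each driver prescribes how the principal direction of differential
growth ``psi_g`` and the drive magnitude ``Delta*Edot`` vary in time
(and, for the two-zone driver, along the organ).  The preset registry
reproduces the simulator's pattern zoo:

===  ==========================================================
key  pattern / mechanism
===  ==========================================================
0    ellipse via rate-modulated rotation  (dpsi_g/dt varies)
1    ellipse via amplitude-modulated drive (Delta*Edot varies)
2    constant direction (alignment, planar bending)
3    circle with proprioceptive regulation
4    circle with whole-organ elongation  (growth spiral)
5    circle with a subapical growth zone (stored basal helix)
===  ==========================================================

plus named two-zone presets ``"epitrochoid"`` / ``"hypotrochoid"``
(a slow basal oscillator under a 6x faster apical one, same |drive|
ratio 1 : 5, the faster one reversed for the hypotrochoid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .core import GrowthDriver

__all__ = [
    "ConstantDriver",
    "UniformRotationDriver",
    "RateModulatedDriver",
    "AmplitudeModulatedDriver",
    "TwoZoneDriver",
    "rate_modulated_period",
    "steady_kappa",
    "PRESETS",
    "make_preset",
    "DEFAULTS",
]

#: Default physical scales shared by the presets: an Arabidopsis-like
#: organ (R = 0.5 mm, L0 = 20 mm) driven at the measured mean rotation
#: rate of the differential-growth direction (4.6e-4 rad/s, a ~228 min
#: period).  delta_edot sets the steady dimensionless curvature
#: |kappa|* = delta_edot/omega to 0.005 (C*L ~ 0.2, safely within the
#: small-curvature regime); edot ~ 7 %/h where elongation matters.
DEFAULTS = {
    "omega": 4.6e-4,  # rad/s
    "radius": 0.5,  # mm
    "length": 20.0,  # mm
    "delta_edot": 0.005 * 4.6e-4,  # 1/s
    "edot": 2e-5,  # 1/s
    "modulation": 0.5,  # S4/S5 depth
}


@dataclass
class ConstantDriver(GrowthDriver):
    """Fixed direction of differential growth: the organ aligns to it."""

    psi_g0: float = 0.0

    def psi_g(self, s, t):
        return np.full_like(np.asarray(s, dtype=float), self.psi_g0)


@dataclass
class UniformRotationDriver(GrowthDriver):
    """psi_g = omega * t, uniform along the organ: the circular pattern."""

    omega: float = DEFAULTS["omega"]

    def psi_g(self, s, t):
        return np.full_like(np.asarray(s, dtype=float), self.omega * t)


@dataclass
class RateModulatedDriver(GrowthDriver):
    """Internal oscillator with a direction-dependent rotation rate:

        dpsi_g/dt = omega0 * (1 + a * cos(2 psi_g))

    The rotation lingers near psi_g = +/- pi/2 (for a > 0), so the organ
    has more time to curve out there: an elliptical pattern with its
    major axis along y.  The phase is integrated as an internal state in
    lockstep with the organ (one classical RK4 substep per dt).
    """

    omega0: float = DEFAULTS["omega"]
    a: float = DEFAULTS["modulation"]
    phase0: float = 0.0
    _phase: float = field(default=None, repr=False)  # type: ignore[assignment]
    _phase_time: float = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        super().__post_init__()
        if not abs(self.a) < 1:
            raise ValueError("|a| must be < 1 to keep the rate positive")
        if self._phase is None:
            self._phase = self.phase0
            self._phase_time = 0.0

    def _rate(self, psi: float) -> float:
        return self.omega0 * (1.0 + self.a * math.cos(2.0 * psi))

    def _integrate(self, psi: float, dt: float) -> float:
        k1 = self._rate(psi)
        k2 = self._rate(psi + 0.5 * dt * k1)
        k3 = self._rate(psi + 0.5 * dt * k2)
        k4 = self._rate(psi + dt * k3)
        return psi + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0

    def psi_g(self, s, t):
        psi = self._phase
        lag = t - self._phase_time
        if abs(lag) > 0:  # e.g. a midpoint half-step query
            psi = self._integrate(psi, lag)
        return np.full_like(np.asarray(s, dtype=float), psi)

    def advance(self, t, dt):
        self._phase = self._integrate(self._phase, dt)
        self._phase_time = t + dt


@dataclass
class AmplitudeModulatedDriver(GrowthDriver):
    """Uniform rotation with a direction-dependent drive magnitude:

        psi_g = omega0 * t,   Delta*Edot = delta_edot * (1 + a cos(2 psi_g))

    The drive is strongest near psi_g = 0, pi (for a > 0): an elliptical
    pattern with its major axis along x — rotated by pi/2 from the
    rate-modulated mechanism at equal depth.
    """

    omega0: float = DEFAULTS["omega"]
    a: float = DEFAULTS["modulation"]

    def __post_init__(self):
        super().__post_init__()
        if not abs(self.a) < 1:
            raise ValueError("|a| must be < 1 to keep the drive positive")

    def psi_g(self, s, t):
        return np.full_like(np.asarray(s, dtype=float), self.omega0 * t)

    def delta_edot_at(self, s, t):
        psi = self.omega0 * t
        val = self.delta_edot * (1.0 + self.a * np.cos(2.0 * psi))
        return np.full_like(np.asarray(s, dtype=float), val)


@dataclass
class TwoZoneDriver(GrowthDriver):
    """Two organ sections with independent linear oscillators.

    The basal fraction ``split`` of the organ follows psi_g = omega1 * t
    with drive ``delta_edot``; the apical remainder follows
    psi_g = omega2 * t with drive ``delta2_edot``.  Superposing the two
    uniformly-curved sections traces a trochoid at the tip (epitrochoid
    for same-sign rates, hypotrochoid for opposite signs).
    """

    omega1: float = DEFAULTS["omega"]
    omega2: float = 6 * DEFAULTS["omega"]
    split: float = 0.5
    delta2_edot: float = 5 * DEFAULTS["delta_edot"]
    #: explicit zone boundary in mm; when None, ``split`` times the
    #: organ's current length (resolved in :meth:`sample`)
    boundary: float | None = None

    def __post_init__(self):
        super().__post_init__()
        if not 0 < self.split < 1:
            raise ValueError("split must be a fraction in (0, 1)")
        if self.delta2_edot < 0:
            raise ValueError("delta2_edot must be non-negative")

    def _basal_mask(self, s, organ_length=None):
        s = np.asarray(s, dtype=float)
        L1 = self.boundary
        if L1 is None:
            if organ_length is None:
                raise ValueError(
                    "TwoZoneDriver needs the organ length (or an explicit "
                    "boundary) to dispatch on s"
                )
            L1 = self.split * organ_length
        return s < L1

    def psi_g(self, s, t, organ_length=None):
        basal = self._basal_mask(s, organ_length)
        return np.where(basal, self.omega1 * t, self.omega2 * t)

    def delta_edot_at(self, s, t, organ_length=None):
        basal = self._basal_mask(s, organ_length)
        return np.where(basal, self.delta_edot, self.delta2_edot)

    def sample(self, s, t, organ_length):
        s = np.asarray(s, dtype=float)
        edot = self.edot_at(s, t)
        dedot = self.delta_edot_at(s, t, organ_length)
        psi = self.psi_g(s, t, organ_length)
        if np.isfinite(self.growth_zone) and organ_length > self.growth_zone:
            frozen = s < organ_length - self.growth_zone
            edot = np.where(frozen, 0.0, edot)
            dedot = np.where(frozen, 0.0, dedot)
        return edot, dedot, psi


def rate_modulated_period(omega0: float, a: float) -> float:
    """Exact time for one full rotation of the rate-modulated oscillator.

    Integrating dt = dpsi / (omega0 (1 + a cos 2 psi)) over a turn gives
    ``2 pi / (omega0 sqrt(1 - a^2))``; even in ``a``.
    """
    if not abs(a) < 1:
        raise ValueError("|a| must be < 1")
    return 2.0 * np.pi / (omega0 * math.sqrt(1.0 - a * a))


def steady_kappa(
    delta_edot: float, omega: float, damping: float = 0.0, t: float = 0.0
) -> np.ndarray:
    """Curvature vector on the periodic orbit of a uniformly rotating drive.

    For d kappa/dt = delta_edot e(omega t) - damping * kappa the attracting
    orbit is a circle of radius ``delta_edot / hypot(omega, damping)``;
    this returns the orbit point at time ``t``, the natural initial
    condition for a centered circular pattern.
    """
    z = delta_edot * np.exp(1j * omega * t) / (damping + 1j * omega)
    return np.array([z.real, z.imag])


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------


def _p0(**kw):
    d = {**DEFAULTS, **kw}
    return RateModulatedDriver(
        edot=0.0, delta_edot=d["delta_edot"], elongates=False,
        omega0=d["omega"], a=d["modulation"],
    )


def _p1(**kw):
    d = {**DEFAULTS, **kw}
    return AmplitudeModulatedDriver(
        edot=0.0, delta_edot=d["delta_edot"], elongates=False,
        omega0=d["omega"], a=d["modulation"],
    )


def _p2(**kw):
    d = {**DEFAULTS, **kw}
    return ConstantDriver(
        edot=0.0, delta_edot=d["delta_edot"], elongates=False,
        psi_g0=d.get("psi_g0", 0.0),
    )


def _p3(**kw):
    d = {**DEFAULTS, **kw}
    # damping rate gamma*edot/R set equal to omega: strong regulation on
    # the oscillation's own time scale
    edot = d["edot"]
    gamma = d.get("gamma", d["omega"] * d["radius"] / edot)
    return UniformRotationDriver(
        edot=edot, delta_edot=d["delta_edot"], gamma=gamma,
        elongates=False, omega=d["omega"],
    )


def _p4(**kw):
    d = {**DEFAULTS, **kw}
    return UniformRotationDriver(
        edot=d["edot"], delta_edot=d["delta_edot"], elongates=True,
        omega=d["omega"],
    )


def _p5(**kw):
    d = {**DEFAULTS, **kw}
    return UniformRotationDriver(
        edot=d["edot"], delta_edot=d["delta_edot"], elongates=True,
        growth_zone=d.get("growth_zone", d["length"] / 2), omega=d["omega"],
    )


def _epi(**kw):
    d = {**DEFAULTS, **kw}
    return TwoZoneDriver(
        edot=0.0, delta_edot=d["delta_edot"], elongates=False,
        omega1=d["omega"], omega2=6 * d["omega"],
        delta2_edot=5 * d["delta_edot"], split=d.get("split", 0.5),
    )


def _hypo(**kw):
    d = {**DEFAULTS, **kw}
    return TwoZoneDriver(
        edot=0.0, delta_edot=d["delta_edot"], elongates=False,
        omega1=d["omega"], omega2=-6 * d["omega"],
        delta2_edot=5 * d["delta_edot"], split=d.get("split", 0.5),
    )


PRESETS = {
    0: _p0,
    1: _p1,
    2: _p2,
    3: _p3,
    4: _p4,
    5: _p5,
    "epitrochoid": _epi,
    "hypotrochoid": _hypo,
}

PRESET_LABELS = {
    0: "ellipse (rate-modulated rotation)",
    1: "ellipse (amplitude-modulated drive)",
    2: "constant direction (alignment)",
    3: "circle + proprioception",
    4: "circle + whole-organ growth (spiral)",
    5: "circle + subapical growth zone",
    "epitrochoid": "two-zone, omega2 = +6 omega1",
    "hypotrochoid": "two-zone, omega2 = -6 omega1",
}


def make_preset(key, **overrides) -> GrowthDriver:
    """Instantiate a preset driver, optionally overriding its parameters.

    ``key`` is one of the integer simulator keys 0-5 or the names
    ``"epitrochoid"`` / ``"hypotrochoid"``; string digits are accepted.
    """
    if isinstance(key, str) and key.isdigit():
        key = int(key)
    try:
        factory = PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown preset {key!r}; choose from {sorted(PRESETS, key=str)}"
        ) from None
    return factory(**overrides)
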