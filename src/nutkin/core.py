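"""Differential-growth kinematics of a cylindrical plant organ.

The organ is a cylinder of constant radius ``R`` described by its median
line: an ordered chain of material (co-moving) segments, each carrying a
rest length, a curvature magnitude ``C`` and a curvature direction
``psi_c`` measured in the cross-section from a reference director that is
transported without twist along the organ.

Growth enters through three fields: the median elongation rate ``Edot``,
the differential-growth drive ``delta_edot`` (the product Delta*Edot, the
rate at which the dimensionless curvature ``C*R`` is pushed), and the
principal direction of differential growth ``psi_g`` — the cross-section
angle the organ bends toward (the slower-growing flank).

The evolution law is integrated on the curvature vector

    kappa = C*R * (cos psi_c, sin psi_c),

which is regular at C = 0 (the polar form is singular there):

    d kappa / dt = delta_edot * (cos psi_g, sin psi_g)
                   - (gamma * Edot / R) * kappa,

optionally carrying the (1 - C^2 R^2) geometric prefactor on the in-plane
component.  ``(C, psi_c)`` are derived views of ``kappa``.

Because segments are material, the advective part of the material
derivative D/Dt = d/dt + v d/ds is realized implicitly: abscissae are
recomputed from the accumulated rest lengths after each elongation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "MaterialSegment",
    "OrganState",
    "GrowthDriver",
    "StrainProfile",
    "surface_segment_length",
    "finite_strain",
    "strain_rate_field",
    "differential_growth_pair",
    "project_growth",
    "step_segment",
    "advance_organ",
]

TWO_PI = 2.0 * np.pi


class GeometryError(ValueError):
    """Raised when a configuration stops being a valid bent cylinder (C*R >= 1)."""


def _wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + np.pi) % TWO_PI - np.pi)
    return w if w.ndim else float(w)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialSegment:
    """One material element of the organ's median line.

    Parameters
    ----------
    rest_length : float
        Median-line length of the element, mm. Positive.
    curv : float
        Curvature magnitude ``C``, 1/mm. Non-negative.
    psi_c : float
        Direction of the principal curvature in the cross-section, rad,
        measured from the transported reference director; stored in
        (-pi, pi]. Undefined (kept as last known value, 0 for a
        never-curved element) when ``curv`` is zero.
    """

    rest_length: float
    curv: float = 0.0
    psi_c: float = 0.0

    def __post_init__(self):
        if not self.rest_length > 0:
            raise ValueError(f"rest_length must be positive, got {self.rest_length}")
        if self.curv < 0:
            raise ValueError(f"curv must be non-negative, got {self.curv}")
        object.__setattr__(self, "psi_c", _wrap_angle(self.psi_c))

    def validate_radius(self, radius: float) -> None:
        if self.curv * radius >= 1.0:
            raise GeometryError(
                f"C*R = {self.curv * radius:.3g} >= 1: inner surface fiber length "
                "would be non-positive"
            )

    @property
    def kappa(self) -> np.ndarray:
        """Dimensionless curvature vector ``C*R*(cos psi_c, sin psi_c)`` needs R.

        Use :meth:`kappa_at` with an explicit radius.
        """
        raise AttributeError("use kappa_at(radius)")

    def kappa_at(self, radius: float) -> np.ndarray:
        cr = self.curv * radius
        return np.array([cr * np.cos(self.psi_c), cr * np.sin(self.psi_c)])


class OrganState:
    """The discrete organ at one instant: radius plus base-to-apex segments.

    Backed by per-segment arrays; :attr:`segments` materializes the typed
    view on demand.
    """

    def __init__(
        self,
        radius: float,
        segments: Sequence[MaterialSegment] | None = None,
        time: float = 0.0,
        *,
        arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    ):
        if not radius > 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.time = float(time)
        if arrays is not None:
            ell, curv, psi = arrays
        elif segments:
            ell = np.array([s.rest_length for s in segments])
            curv = np.array([s.curv for s in segments])
            psi = np.array([s.psi_c for s in segments])
        else:
            raise ValueError("organ needs at least one segment")
        self._ell = np.asarray(ell, dtype=float)
        self._curv = np.asarray(curv, dtype=float)
        self._psi = np.asarray(psi, dtype=float)
        if self._ell.size == 0:
            raise ValueError("organ needs at least one segment")
        if np.any(self._ell <= 0):
            raise ValueError("rest lengths must be positive")
        if np.any(self._curv < 0):
            raise ValueError("curvatures must be non-negative")
        bad = self._curv * self.radius >= 1.0
        if np.any(bad):
            i = int(np.argmax(bad))
            raise GeometryError(
                f"segment {i}: C*R = {self._curv[i] * self.radius:.3g} >= 1"
            )

    def __repr__(self):
        return (
            f"OrganState(radius={self.radius}, n_segments={self.n_segments}, "
            f"time={self.time}, length={self.length:.6g})"
        )

    # -- views -------------------------------------------------------------

    @property
    def segments(self) -> list[MaterialSegment]:
        return [
            MaterialSegment(float(l), float(c), float(p))
            for l, c, p in zip(self._ell, self._curv, self._psi)
        ]

    @property
    def n_segments(self) -> int:
        return int(self._ell.size)

    @property
    def rest_lengths(self) -> np.ndarray:
        return self._ell.copy()

    @property
    def curvatures(self) -> np.ndarray:
        return self._curv.copy()

    @property
    def psi_cs(self) -> np.ndarray:
        return self._psi.copy()

    @property
    def length(self) -> float:
        return float(self._ell.sum())

    @property
    def abscissae(self) -> np.ndarray:
        """Base abscissa s of each segment (base-anchored cumulative sum)."""
        return np.concatenate([[0.0], np.cumsum(self._ell)[:-1]])

    @property
    def boundaries(self) -> np.ndarray:
        """Abscissae of the n+1 segment boundaries, base 0 to apex L."""
        return np.concatenate([[0.0], np.cumsum(self._ell)])

    def kappas(self) -> np.ndarray:
        """(n, 2) array of dimensionless curvature vectors C*R*(cos, sin)psi_c."""
        cr = self._curv * self.radius
        return np.column_stack([cr * np.cos(self._psi), cr * np.sin(self._psi)])

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(
        cls,
        radius: float,
        length: float,
        n_segments: int = 100,
        curv: float = 0.0,
        psi_c: float = 0.0,
        time: float = 0.0,
    ) -> "OrganState":
        """Organ with uniform curvature and direction along its length."""
        ell = length / n_segments
        segs = [MaterialSegment(ell, curv, psi_c) for _ in range(n_segments)]
        return cls(radius, segs, time)

    @classmethod
    def from_arrays(
        cls,
        radius: float,
        rest_lengths: np.ndarray,
        kappas: np.ndarray,
        time: float = 0.0,
        prev_psi: np.ndarray | None = None,
    ) -> "OrganState":
        """Build from per-segment rest lengths and curvature vectors.

        ``prev_psi`` supplies the reported direction for segments whose
        curvature vector vanishes (the direction of the last nonzero kappa).
        """
        kappas = np.asarray(kappas, dtype=float)
        cr = np.hypot(kappas[:, 0], kappas[:, 1])
        psi = np.arctan2(kappas[:, 1], kappas[:, 0])
        if prev_psi is not None:
            psi = np.where(cr > 0, psi, prev_psi)
        return cls(
            radius,
            time=time,
            arrays=(np.asarray(rest_lengths, dtype=float), cr / radius, psi),
        )


@dataclass
class StrainProfile:
    """Elongation strain rates sampled on cross-section angles phi."""

    phis: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.phis = np.asarray(self.phis, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.phis.shape != self.rates.shape:
            raise ValueError("phis and rates must have the same shape")


# ---------------------------------------------------------------------------
# growth driver
# ---------------------------------------------------------------------------


@dataclass
class GrowthDriver:
    """Growth program: elongation, differential-growth drive and its direction.

    Subclasses override :meth:`psi_g` (and possibly :meth:`delta_edot_at`)
    to implement time- or space-dependent oscillators.  ``advance`` lets
    drivers with internal state (integrated oscillator phase) move forward
    in lockstep with the organ.

    Parameters
    ----------
    edot : float
        Median elongation rate, 1/s. Non-negative.
    delta_edot : float
        Differential-growth drive Delta*Edot, the rate of change of C*R,
        1/s. Non-negative; direction lives solely in psi_g.
    gamma : float
        Proprioceptive gain, mm (gamma*C is dimensionless). The damping
        rate of the curvature vector is gamma*edot/radius.
    growth_zone : float
        Subapical growth-zone length L_gz, mm. ``inf`` means the whole
        organ grows.
    elongates : bool
        When False, Edot still drives the curvature dynamics (its damping
        role) but rest lengths are held fixed — the paper-style
        "neglect elongation" perturbative regime.
    """

    edot: float = 0.0
    delta_edot: float = 0.0
    gamma: float = 0.0
    growth_zone: float = np.inf
    elongates: bool = True

    def __post_init__(self):
        if self.edot < 0:
            raise ValueError("edot must be non-negative (no compression)")
        if self.delta_edot < 0:
            raise ValueError("delta_edot must be non-negative; use psi_g for direction")

    # -- fields ------------------------------------------------------------

    def psi_g(self, s: np.ndarray, t: float) -> np.ndarray:
        """Principal direction of differential growth at abscissae s, time t."""
        return np.zeros_like(np.asarray(s, dtype=float))

    def edot_at(self, s: np.ndarray, t: float) -> np.ndarray:
        return np.full_like(np.asarray(s, dtype=float), self.edot)

    def delta_edot_at(self, s: np.ndarray, t: float) -> np.ndarray:
        return np.full_like(np.asarray(s, dtype=float), self.delta_edot)

    def sample(self, s: np.ndarray, t: float, organ_length: float):
        """(edot, delta_edot, psi_g) arrays at abscissae s with the growth
        zone applied: material below L - L_gz neither grows nor is driven."""
        s = np.asarray(s, dtype=float)
        edot = self.edot_at(s, t)
        dedot = self.delta_edot_at(s, t)
        psi = self.psi_g(s, t)
        if np.isfinite(self.growth_zone) and organ_length > self.growth_zone:
            frozen = s < organ_length - self.growth_zone
            edot = np.where(frozen, 0.0, edot)
            dedot = np.where(frozen, 0.0, dedot)
        return edot, dedot, psi

    def advance(self, t: float, dt: float) -> None:
        """Advance any internal oscillator state from t to t + dt."""


# ---------------------------------------------------------------------------
# strain kinematics (finite and rate form)
# ---------------------------------------------------------------------------


def surface_segment_length(L0, C, R, psi_c, phi):
    """Length of the surface fiber at cross-section angle phi.

    For a cylinder element of median length ``L0`` bent to curvature ``C``
    toward ``psi_c``, the fiber at angle ``phi`` has length
    ``L0 * (1 - C*R*cos(phi - psi_c))``: shortest on the concave flank
    (phi = psi_c), longest on the convex one.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C * R >= 1.0):
        raise GeometryError("C*R >= 1: inner fiber length would be non-positive")
    if np.any(np.asarray(L0) <= 0):
        raise ValueError("L0 must be positive")
    out = L0 * (1.0 - C * R * np.cos(np.asarray(phi, dtype=float) - psi_c))
    return out if out.ndim else float(out)


def finite_strain(before, after, R, phi):
    """Elongation strain eps(phi) between two bent-cylinder configurations.

    ``before`` and ``after`` are ``(L0, C, psi_c)`` triples.  Returns
    ``L_s'(phi) / L_s(phi) - 1`` evaluated fiber-by-fiber; this is the
    brute-force oracle for :func:`strain_rate_field`.
    """
    L0a, Ca, pa = before
    L0b, Cb, pb = after
    ls_a = surface_segment_length(L0a, Ca, R, pa, phi)
    ls_b = surface_segment_length(L0b, Cb, R, pb, phi)
    return ls_b / ls_a - 1.0


def strain_rate_field(
    seg: MaterialSegment,
    R: float,
    dCR_dt: float,
    dpsi_dt: float,
    edot: float,
    phis: np.ndarray,
) -> StrainProfile:
    """Elongation strain rate around the cross-section.

    Exact first-order rate of :func:`finite_strain` along the configuration
    path ``(L0 e^{edot t}, C(t), psi_c(t))`` with ``d(CR)/dt = dCR_dt`` and
    ``d psi_c/dt = dpsi_dt``:

        eps_dot(phi) = edot
            - [cos(phi - psi_c) * dCR_dt + C*R * sin(phi - psi_c) * dpsi_dt]
              / (1 - C*R*cos(phi - psi_c))

    The curvature-rate term vanishes at phi = psi_c +/- pi/2 and the
    direction-rate term at phi in {psi_c, psi_c + pi}: the two
    contributions dominate in orthogonal planes.
    """
    seg.validate_radius(R)
    phis = np.asarray(phis, dtype=float)
    beta = phis - seg.psi_c
    cr = seg.curv * R
    denom = 1.0 - cr * np.cos(beta)
    rates = edot - (np.cos(beta) * dCR_dt + cr * np.sin(beta) * dpsi_dt) / denom
    return StrainProfile(phis, rates)


def _interp_rate(profile: StrainProfile, phi: float) -> float:
    """Periodic linear interpolation of a strain profile at angle phi."""
    phis = np.mod(profile.phis, TWO_PI)
    order = np.argsort(phis)
    xp = phis[order]
    fp = profile.rates[order]
    # pad one period each side for wrap-around
    xp = np.concatenate([xp[-1:] - TWO_PI, xp, xp[:1] + TWO_PI])
    fp = np.concatenate([fp[-1:], fp, fp[:1]])
    return float(np.interp(np.mod(phi, TWO_PI), xp, fp))


def differential_growth_pair(profile: StrainProfile, psi_c: float, edot: float):
    """Differential growth in the plane of curvature and orthogonal to it.

    The asymmetry is signed so that positive Delta(phi) means the flank at
    ``phi`` grows *slower* than the opposite one — the organ bends toward
    phi:

        Delta(phi) = (eps_dot(phi + pi) - eps_dot(phi)) / (2 edot)

    Returns ``(Delta_par, Delta_perp) = (Delta(psi_c), Delta(psi_c + pi/2))``.
    |Delta| = 1 corresponds to all growth on one flank.
    """
    if edot == 0:
        raise ZeroDivisionError("differential growth undefined at edot = 0")
    d_par = (_interp_rate(profile, psi_c + np.pi) - _interp_rate(profile, psi_c)) / (
        2.0 * edot
    )
    d_perp = (
        _interp_rate(profile, psi_c + 1.5 * np.pi)
        - _interp_rate(profile, psi_c + 0.5 * np.pi)
    ) / (2.0 * edot)
    return d_par, d_perp


def project_growth(delta_max: float, psi_g: float, psi_c: float):
    """Project the principal differential growth onto the curvature frame.

    Returns ``(Delta_par, Delta_perp) = Delta * (cos, sin)(psi_g - psi_c)``.
    """
    if delta_max < 0:
        raise ValueError("delta_max must be non-negative")
    return (
        delta_max * np.cos(psi_g - psi_c),
        delta_max * np.sin(psi_g - psi_c),
    )


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def _kappa_rate(
    kappa: np.ndarray,
    edot,
    delta_edot,
    psi_g,
    gamma: float,
    R: float,
    keep_quadratic: bool,
) -> np.ndarray:
    """Right-hand side of the curvature-vector evolution, vectorized (n, 2)."""
    drive = np.stack(
        [delta_edot * np.cos(psi_g), delta_edot * np.sin(psi_g)], axis=-1
    )
    if keep_quadratic:
        # the (1 - C^2 R^2) prefactor applies to the in-plane component only
        k2 = np.sum(kappa * kappa, axis=-1, keepdims=True)
        norm = np.sqrt(k2)
        with np.errstate(invalid="ignore", divide="ignore"):
            khat = np.where(norm > 0, kappa / np.where(norm > 0, norm, 1.0), 0.0)
        par = np.sum(drive * khat, axis=-1, keepdims=True) * khat
        perp = drive - par
        drive = par * (1.0 - k2) + perp
    damp = (gamma * np.atleast_1d(edot)[..., None] / R) * kappa
    return drive - damp


def step_segment(
    seg: MaterialSegment,
    R: float,
    edot: float,
    delta_edot: float,
    psi_g: float,
    gamma: float,
    dt: float,
    keep_quadratic: bool = False,
    elongate: bool = True,
) -> MaterialSegment:
    """Advance one material segment by an explicit Euler step of dt seconds.

    The curvature vector kappa = C*R*(cos psi_c, sin psi_c) receives
    ``dt * [delta_edot*(cos psi_g, sin psi_g) - (gamma*edot/R)*kappa]`` and
    the rest length is multiplied by ``1 + edot*dt`` (when ``elongate``).
    With ``keep_quadratic`` the in-plane drive carries the geometric
    (1 - C^2 R^2) factor.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    seg.validate_radius(R)
    kappa = seg.kappa_at(R)
    kappa = kappa + dt * _kappa_rate(
        kappa[None, :], edot, delta_edot, psi_g, gamma, R, keep_quadratic
    )[0]
    cr = float(np.hypot(*kappa))
    if cr >= 1.0:
        raise GeometryError(
            f"step drove C*R to {cr:.3g} >= 1; reduce dt or add proprioception"
        )
    psi = float(np.arctan2(kappa[1], kappa[0])) if cr > 0 else seg.psi_c
    ell = seg.rest_length * (1.0 + edot * dt) if elongate else seg.rest_length
    return MaterialSegment(ell, cr / R, psi)


def advance_organ(
    organ: OrganState,
    driver: GrowthDriver,
    dt: float,
    keep_quadratic: bool = False,
    scheme: str = "euler",
) -> OrganState:
    """Advance the whole organ by one time step (vectorized over segments).

    Driver fields are evaluated at each segment's current base abscissa.
    Because segments are material, advection is implicit: abscissae are
    recomputed from the accumulated rest lengths of the elongated chain.
    Material below ``L - L_gz`` receives edot = 0 and stays frozen.

    ``scheme`` is ``"euler"`` (default, matching the first-order
    derivation) or ``"midpoint"`` (second-order in dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    R = organ.radius
    s = organ.abscissae
    L = organ.length
    t = organ.time
    kappa = organ.kappas()

    edot, dedot, psi_g = driver.sample(s, t, L)
    k1 = _kappa_rate(kappa, edot, dedot, psi_g, driver.gamma, R, keep_quadratic)
    if scheme == "euler":
        kappa_new = kappa + dt * k1
    elif scheme == "midpoint":
        kappa_half = kappa + 0.5 * dt * k1
        edot2, dedot2, psi_g2 = driver.sample(s, t + 0.5 * dt, L)
        k2 = _kappa_rate(
            kappa_half, edot2, dedot2, psi_g2, driver.gamma, R, keep_quadratic
        )
        kappa_new = kappa + dt * k2
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    cr = np.hypot(kappa_new[:, 0], kappa_new[:, 1])
    if np.any(cr >= 1.0):
        i = int(np.argmax(cr))
        raise GeometryError(
            f"segment {i} reached C*R = {cr[i]:.3g} >= 1 at t = {t + dt:.6g} s; "
            "reduce dt or add proprioception"
        )
    if driver.elongates:
        ell = organ.rest_lengths * (1.0 + edot * dt)
    else:
        ell = organ.rest_lengths
    psi = np.arctan2(kappa_new[:, 1], kappa_new[:, 0])
    # untouched segments keep their stored (C, psi_c) bit-for-bit (avoids
    # polar->cartesian->polar rounding churn on frozen material)
    unchanged = np.all(kappa_new == kappa, axis=1)
    cr = np.where(unchanged, organ._curv * R, cr)
    psi = np.where(unchanged | (cr == 0), organ._psi, psi)
    return OrganState(R, time=t + dt, arrays=(ell, cr / R, psi))
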