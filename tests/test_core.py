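"""Unit and property tests for the strain kinematics and time stepping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutkin.core import (
    GeometryError,
    GrowthDriver,
    MaterialSegment,
    OrganState,
    advance_organ,
    differential_growth_pair,
    finite_strain,
    project_growth,
    step_segment,
    strain_rate_field,
    surface_segment_length,
)
from nutkin.drivers import ConstantDriver, UniformRotationDriver, steady_kappa

PHIS = np.linspace(-np.pi, np.pi, 181, endpoint=False)


# ---------------------------------------------------------------------------
# surface fibers and finite strain
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "L0, C, R, psi_c, phi, expected",
    [
        (1.5, 0.2, 1.0, 0.3, 0.3, 1.5 * (1 - 0.2)),  # concave flank: minimal
        (1.5, 0.0, 1.0, 0.0, 2.1, 1.5),  # straight cylinder
        (2.0, 0.1, 1.0, 0.0, np.pi, 2.2),  # convex flank: maximal
    ],
)
def test_surface_fiber_length(L0, C, R, psi_c, phi, expected):
    assert surface_segment_length(L0, C, R, psi_c, phi) == pytest.approx(expected)


def test_surface_fiber_rejects_overbent():
    with pytest.raises(GeometryError):
        surface_segment_length(1.0, 1.1, 1.0, 0.0, 0.0)


def test_finite_strain_trivial_cases():
    before = (1.0, 0.3, 0.2)
    assert finite_strain(before, before, 0.5, PHIS) == pytest.approx(0.0)
    # pure uniform elongation: strain is the median elongation everywhere
    strains = finite_strain((1.0, 0.0, 0.0), (1.1, 0.0, 0.0), 0.5, PHIS)
    np.testing.assert_allclose(strains, 0.1, rtol=1e-12)


def test_finite_strain_mean_tracks_median_elongation():
    """The cross-section average strain equals the median-line elongation
    exactly for straight configurations and to O((C R)^2) for bent ones."""
    phis = np.linspace(-np.pi, np.pi, 360, endpoint=False)
    # straight: exact
    mean = finite_strain((2.0, 0.0, 0.0), (2.5, 0.0, 0.0), 0.5, phis).mean()
    assert mean == pytest.approx(0.25, abs=1e-14)
    # bent, reorienting: median length unchanged -> mean strain ~ 0 with a
    # quadratic-in-CR bias (CR = 0.05 here, bias ~ CR^2/2)
    mean = finite_strain((1.0, 0.1, 0.0), (1.0, 0.1, np.pi / 2), 0.5, phis).mean()
    assert abs(mean) < 0.05**2


# ---------------------------------------------------------------------------
# strain-rate field and its finite-strain oracle
# ---------------------------------------------------------------------------


def test_strain_rate_pure_elongation_is_uniform():
    seg = MaterialSegment(1.0, 0.4, 0.7)
    prof = strain_rate_field(seg, 0.5, dCR_dt=0.0, dpsi_dt=0.0, edot=0.3, phis=PHIS)
    np.testing.assert_allclose(prof.rates, 0.3, rtol=1e-12)


def test_strain_rate_straight_segment_pure_bending():
    # C = 0: denominator is 1 and the direction-rate term is killed
    seg = MaterialSegment(1.0, 0.0, 0.4)
    prof = strain_rate_field(seg, 0.5, dCR_dt=0.2, dpsi_dt=5.0, edot=0.1, phis=PHIS)
    np.testing.assert_allclose(
        prof.rates, 0.1 - 0.2 * np.cos(PHIS - 0.4), rtol=1e-12
    )


def test_strain_rate_orthogonal_contributions():
    """Curvature-rate acts in the plane of curvature, direction-rate in the
    orthogonal plane."""
    seg = MaterialSegment(1.0, 0.3, 0.5)
    # grid anchored at psi_c so the four cardinal angles are exact nodes
    phis = 0.5 + np.linspace(-np.pi, np.pi, 180, endpoint=False)
    base = strain_rate_field(seg, 0.8, 0.0, 0.0, 0.2, phis).rates
    bend = strain_rate_field(seg, 0.8, 0.1, 0.0, 0.2, phis).rates
    turn = strain_rate_field(seg, 0.8, 0.0, 0.1, 0.2, phis).rates
    at = lambda rates, phi: np.interp(phi, phis, rates, period=2 * np.pi)
    for phi in (0.5 + np.pi / 2, 0.5 - np.pi / 2):
        assert at(bend, phi) == pytest.approx(at(base, phi), abs=1e-12)
    for phi in (0.5, 0.5 + np.pi):
        assert at(turn, phi) == pytest.approx(at(base, phi), abs=1e-12)


def test_strain_rate_matches_finite_strain_to_first_order(rng):
    """finite_strain(before, after)/dt converges to the rate field linearly
    in dt: the error halves when dt halves (first-order oracle equivalence)."""
    for _ in range(20):
        C = rng.uniform(0.0, 0.85)
        psi = rng.uniform(-np.pi, np.pi)
        edot = rng.uniform(0.05, 1.0)
        kdot = rng.normal(size=2) * 0.3
        errs = []
        for dt in (1e-3, 5e-4):
            k0 = np.array([C * np.cos(psi), C * np.sin(psi)])
            k1 = k0 + dt * kdot
            C1, psi1 = np.hypot(*k1), np.arctan2(k1[1], k1[0])
            rate_oracle = (
                finite_strain(
                    (1.0, C, psi), (1.0 + edot * dt, C1, psi1), 1.0, PHIS
                )
                / dt
            )
            dCR = (C1 - C) / dt
            dpsi = (np.unwrap([psi, psi1])[1] - psi) / dt
            prof = strain_rate_field(
                MaterialSegment(1.0, C, psi), 1.0, dCR, dpsi, edot, PHIS
            )
            errs.append(np.max(np.abs(rate_oracle - prof.rates)))
        if errs[0] > 1e-12:
            assert errs[1] < 0.7 * errs[0]  # strictly first order or better


# ---------------------------------------------------------------------------
# differential growth projections
# ---------------------------------------------------------------------------


def test_differential_growth_uniform_profile_is_zero():
    from nutkin.core import StrainProfile

    prof = StrainProfile(PHIS, np.full_like(PHIS, 0.3))
    assert differential_growth_pair(prof, 0.7, 0.3) == pytest.approx((0.0, 0.0))


def test_differential_growth_symmetric_profile_has_no_perp():
    from nutkin.core import StrainProfile

    psi_c = 0.9
    phis = psi_c + np.linspace(-np.pi, np.pi, 180, endpoint=False)
    prof = StrainProfile(phis, 0.2 + 0.05 * np.cos(phis - psi_c))
    _, d_perp = differential_growth_pair(prof, psi_c, 0.2)
    assert d_perp == pytest.approx(0.0, abs=1e-12)


def test_differential_growth_requires_positive_edot():
    from nutkin.core import StrainProfile

    with pytest.raises(ZeroDivisionError):
        differential_growth_pair(StrainProfile(PHIS, PHIS * 0), 0.0, 0.0)


def test_differential_growth_roundtrip_through_evolution_laws(rng):
    """Rates -> strain profile -> (Delta_par, Delta_perp) -> rates recovers
    d(CR)/dt and CR * dpsi_c/dt through the evolution laws exactly."""
    for _ in range(10):
        C, R = rng.uniform(0.05, 0.8), 1.0
        psi = rng.uniform(-np.pi, np.pi)
        edot = rng.uniform(0.1, 1.0)
        dCR, dpsi = rng.normal(size=2) * 0.2
        seg = MaterialSegment(1.0, C, psi)
        # grid anchored at psi_c: cardinal angles sampled exactly
        phis = psi + np.linspace(-np.pi, np.pi, 720, endpoint=False)
        prof = strain_rate_field(seg, R, dCR, dpsi, edot, phis)
        d_par, d_perp = differential_growth_pair(prof, psi, edot)
        # in-plane law carries the quadratic geometric factor
        assert d_par * edot * (1 - (C * R) ** 2) == pytest.approx(dCR, abs=1e-9)
        assert d_perp * edot / (C * R) == pytest.approx(dpsi, abs=1e-9)


@pytest.mark.parametrize(
    "delta, dpsi, expected",
    [
        (0.8, 0.0, (0.8, 0.0)),
        (0.8, np.pi / 2, (0.0, 0.8)),
        (1.0, np.pi / 3, (0.5, np.sqrt(3) / 2)),
    ],
)
def test_project_growth(delta, dpsi, expected):
    psi_c = 0.4
    out = project_growth(delta, psi_c + dpsi, psi_c)
    assert out == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# single-segment stepping
# ---------------------------------------------------------------------------


def test_step_segment_passive_drift():
    seg = MaterialSegment(1.0, 0.2, 0.5)
    out = step_segment(seg, 1.0, edot=0.1, delta_edot=0.0, psi_g=0.0, gamma=0.0,
                       dt=0.01)
    assert out.curv == pytest.approx(seg.curv)
    assert out.psi_c == pytest.approx(seg.psi_c)
    assert out.rest_length == pytest.approx(1.0 * 1.001)


def test_step_segment_aligned_drive_grows_linearly():
    seg = MaterialSegment(1.0, 0.1, 0.0)
    out = step_segment(seg, 1.0, edot=0.0, delta_edot=0.5, psi_g=0.0, gamma=0.0,
                       dt=0.01)
    assert out.curv == pytest.approx(0.1 + 0.5 * 0.01)
    assert out.psi_c == pytest.approx(0.0)


def test_step_segment_tanh_limit_with_quadratic_factor():
    """From straight, an aligned drive with the geometric prefactor follows
    C R(t) = tanh(delta_edot * t)."""
    seg = MaterialSegment(1.0)
    dt = 1e-4
    for _ in range(int(2.0 / dt)):
        seg = step_segment(seg, 1.0, 0.0, 1.0, 0.0, 0.0, dt,
                           keep_quadratic=True, elongate=False)
    assert seg.curv == pytest.approx(np.tanh(2.0), abs=1e-4)


def test_step_segment_rejects_overbending():
    seg = MaterialSegment(1.0, 0.9, 0.0)
    with pytest.raises(GeometryError):
        step_segment(seg, 1.0, 0.0, 1.0, 0.0, 0.0, dt=0.5)


# ---------------------------------------------------------------------------
# whole-organ stepping
# ---------------------------------------------------------------------------


def test_advance_organ_pure_dilation():
    organ = OrganState.uniform(0.5, 10.0, 20, curv=0.05, psi_c=0.3)
    driver = GrowthDriver(edot=0.01)
    out = advance_organ(organ, driver, dt=1.0)
    np.testing.assert_allclose(out.curvatures, 0.05, rtol=1e-12)
    np.testing.assert_allclose(out.abscissae, organ.abscissae * 1.01, rtol=1e-12)


def test_advance_organ_conservation_without_drive():
    """No differential growth, no proprioception: (C, psi_c) are bit-stable
    and lengths compound exactly by (1 + edot dt)."""
    organ = OrganState.uniform(0.5, 10.0, 20, curv=0.05, psi_c=0.3)
    driver = GrowthDriver(edot=0.01)
    state = organ
    for _ in range(10):
        state = advance_organ(state, driver, dt=1.0)
    assert np.all(state.curvatures == organ.curvatures)
    assert np.all(state.psi_cs == organ.psi_cs)
    np.testing.assert_allclose(
        state.rest_lengths, organ.rest_lengths * 1.01**10, rtol=1e-14
    )


def test_advance_organ_growth_zone_freezes_base():
    """Material below L - L_gz stops moving; its stored directions form the
    non-planar record of the rotation it saw when leaving the zone."""
    driver = UniformRotationDriver(
        edot=1e-3, delta_edot=5e-4, growth_zone=5.0, omega=2e-3
    )
    organ = OrganState.uniform(0.5, 10.0, 40)
    state = organ
    for _ in range(400):
        state = advance_organ(state, driver, dt=5.0)
    s = state.abscissae
    frozen = s < state.length - 5.0
    assert frozen.sum() > 5
    # frozen segments retain distinct psi_c stored at zone exit
    stored = state.psi_cs[frozen][state.curvatures[frozen] > 0]
    assert np.ptp(stored) > 0.5
    # one more step leaves frozen segments' curvature state untouched
    nxt = advance_organ(state, driver, dt=5.0)
    n_froz = int(frozen.sum()) - 1  # the boundary segment may change state
    assert np.all(nxt.curvatures[:n_froz] == state.curvatures[:n_froz])
    assert np.all(nxt.rest_lengths[:n_froz] == state.rest_lengths[:n_froz])


def test_advance_organ_velocity_matches_growth_integral():
    """Boundary displacement per unit time equals the cumulative elongation
    integral int_0^s edot ds' within one segment length."""
    driver = UniformRotationDriver(edot=2e-3, delta_edot=0.0, growth_zone=4.0,
                                   omega=1e-3)
    organ = OrganState.uniform(0.5, 10.0, 50)
    dt = 1.0
    out = advance_organ(organ, driver, dt)
    v_measured = (out.boundaries - organ.boundaries) / dt
    s = organ.abscissae
    edot, _, _ = driver.sample(s, 0.0, organ.length)
    v_expected = np.concatenate([[0.0], np.cumsum(edot * organ.rest_lengths)])
    seg_len = organ.rest_lengths[0]
    assert np.max(np.abs(v_measured - v_expected)) < 2e-3 * seg_len


def test_midpoint_scheme_is_higher_order():
    """Against the exact damped-rotation solution, halving dt cuts the Euler
    error ~2x and the midpoint error ~4x."""
    omega, de, lam = 1e-3, 1e-5, 5e-4
    R = 1.0
    driver = UniformRotationDriver(
        edot=lam * R, delta_edot=de, gamma=1.0, omega=omega, elongates=False
    )
    k0 = np.array([0.004, -0.002])
    t_end = 4000.0

    def exact(t):
        z0 = complex(*k0)
        zp = de * np.exp(1j * omega * t) / (lam + 1j * omega)
        zp0 = de / (lam + 1j * omega)
        z = (z0 - zp0) * np.exp(-lam * t) + zp
        return np.array([z.real, z.imag])

    def final_err(scheme, dt):
        organ = OrganState.from_arrays(R, np.full(4, 2.5), np.tile(k0, (4, 1)))
        state = organ
        for _ in range(int(round(t_end / dt))):
            state = advance_organ(state, driver, dt, scheme=scheme)
        return np.linalg.norm(state.kappas()[0] - exact(t_end))

    e1, e2 = final_err("euler", 40.0), final_err("euler", 20.0)
    assert 1.7 < e1 / e2 < 2.3
    m1, m2 = final_err("midpoint", 40.0), final_err("midpoint", 20.0)
    assert m1 / m2 > 3.4
    assert m2 < e2


# ---------------------------------------------------------------------------
# dynamical properties
# ---------------------------------------------------------------------------


def test_alignment_fixed_point():
    """Constant psi_g, no proprioception: psi_c converges monotonically to
    psi_g while curvature grows; once aligned the out-of-plane drive is 0."""
    driver = ConstantDriver(delta_edot=1e-5, psi_g0=1.0, elongates=False,
                            edot=0.0)
    organ = OrganState.uniform(0.5, 10.0, 5, curv=0.01, psi_c=-2.0)
    gaps, curvs = [], []
    state = organ
    for _ in range(300):
        state = advance_organ(state, driver, dt=50.0)
        gaps.append(abs((state.psi_cs[0] - 1.0 + np.pi) % (2 * np.pi) - np.pi))
        curvs.append(state.curvatures[0])
    assert all(b <= a + 1e-15 for a, b in zip(gaps, gaps[1:]))
    assert gaps[-1] < 0.05
    assert curvs[-1] > curvs[0]
    # aligned state: perpendicular projection vanishes identically
    assert project_growth(1.0, 1.0, 1.0)[1] == 0.0


def test_rotating_driver_limit_cycle_is_circle():
    """With psi_g = omega t and no damping, kappa runs on a circle of radius
    delta_edot/omega about a center set by the initial condition; the period
    is 2 pi / omega regardless of that center."""
    omega, de = 1e-3, 1e-5
    driver = UniformRotationDriver(edot=0.0, delta_edot=de, omega=omega,
                                   elongates=False)
    dt = 2.0
    n = int(round(2 * np.pi / omega / dt))
    for k0 in (np.zeros(2), np.array([0.003, 0.001])):
        organ = OrganState.from_arrays(0.5, np.full(3, 3.0), np.tile(k0, (3, 1)))
        state = organ
        pts = []
        for _ in range(2 * n):
            state = advance_organ(state, driver, dt)
            pts.append(state.kappas()[0])
        pts = np.asarray(pts)
        center = 0.5 * (pts.max(axis=0) + pts.min(axis=0))
        radii = np.hypot(*(pts - center).T)
        assert np.ptp(radii) / radii.mean() < 5e-3
        assert radii.mean() == pytest.approx(de / omega, rel=2e-3)
        # periodicity: one full turn returns to the start
        np.testing.assert_allclose(pts[n - 1], pts[2 * n - 1], atol=2e-2 * de / omega)


def test_proprioceptive_attractor_forgets_initial_conditions():
    """With damping gamma*edot/R the rotating orbit has amplitude
    delta_edot/hypot(omega, damping) and any two initial conditions meet
    within 1e-6 (in C*R units) after 10 damping times."""
    omega, de, R = 1e-3, 1e-5, 0.5
    edot, gamma = 1e-4, 5.0  # damping = 1e-3 = omega
    lam = gamma * edot / R
    driver = UniformRotationDriver(edot=edot, delta_edot=de, gamma=gamma,
                                   omega=omega, elongates=False)
    dt = 5.0
    n = int(round(10.0 / lam / dt))
    finals = []
    for k0 in (np.array([0.01, 0.0]), np.array([-0.004, 0.008])):
        organ = OrganState.from_arrays(R, np.full(3, 3.0), np.tile(k0, (3, 1)))
        state = organ
        for _ in range(n):
            state = advance_organ(state, driver, dt)
        finals.append(state.kappas()[0])
    assert np.linalg.norm(finals[0] - finals[1]) < 1e-6
    amp = np.linalg.norm(finals[0])
    assert amp == pytest.approx(de / np.hypot(omega, lam), rel=0.01)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    C=st.floats(0.05, 0.7),
    psi=st.floats(-3.0, 3.0),
    psi_g=st.floats(-3.0, 3.0),
    de=st.floats(1e-6, 1e-4),
)
def test_kappa_update_equals_polar_evolution_laws(C, psi, psi_g, de):
    """One kappa-vector step reproduces the polar evolution laws
    d(CR)/dt = Delta_par Edot, dpsi_c/dt = Delta_perp Edot / (CR) for C > 0."""
    R, dt = 1.0, 1e-3
    seg = MaterialSegment(1.0, C, psi)
    out = step_segment(seg, R, 0.0, de, psi_g, 0.0, dt, elongate=False)
    d_par, d_perp = project_growth(de, psi_g, psi)  # Delta*Edot projections
    dCR = (out.curv - C) * R / dt
    dpsi = ((out.psi_c - psi + np.pi) % (2 * np.pi) - np.pi) / dt
    assert dCR == pytest.approx(d_par, abs=de * dt / R * 10 + 1e-12)
    assert dpsi * C * R == pytest.approx(d_perp, abs=de * dt * 10 + 1e-12)


def test_organ_state_invariants():
    organ = OrganState.uniform(0.5, 10.0, 4, curv=0.1, psi_c=0.2)
    assert organ.length == pytest.approx(10.0)
    np.testing.assert_allclose(organ.abscissae, [0.0, 2.5, 5.0, 7.5])
    with pytest.raises(GeometryError):
        OrganState.uniform(1.0, 10.0, 4, curv=1.5)
    with pytest.raises(ValueError):
        MaterialSegment(-1.0)
    with pytest.raises(ValueError):
        MaterialSegment(1.0, curv=-0.1)
    # psi_c stored wrapped to (-pi, pi]
    assert MaterialSegment(1.0, 0.1, 3 * np.pi / 2).psi_c == pytest.approx(-np.pi / 2)
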