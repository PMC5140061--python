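# Methods

## Model

The organ is an inextensible-cross-section cylinder of constant radius
*R* whose median line carries, per material element, a curvature *C* and
a curvature direction ψ_c measured in the cross-section from a reference
director transported with zero twist.  The kinematic primitive is the
length of a surface fiber at cross-section angle φ of a bent element of
median length L0:

    L_s(φ) = L0 (1 − C R cos(φ − ψ_c)),

shortest on the concave flank.  The finite elongation strain between two
configurations is ε(φ) = L_s′(φ)/L_s(φ) − 1, and its first-order rate
along a configuration path (Ė = median elongation rate, k = C R):

    ε̇(φ) = Ė − [cos(φ−ψ_c) dk/dt + k sin(φ−ψ_c) dψ_c/dt] / (1 − k cos(φ−ψ_c)).

The curvature-rate contribution dominates in the plane of curvature
(φ = ψ_c, ψ_c+π), the direction-rate contribution in the orthogonal
plane (φ = ψ_c ± π/2).

**Sign convention.**  The differential-growth asymmetry is defined as

    Δ(φ) = [ε̇(φ+π) − ε̇(φ)] / (2 Ė),

i.e. positive Δ(φ) means the flank at φ grows *slower* than its opposite
and the organ bends toward φ.  With this convention the projections
Δ_par = Δ(ψ_c), Δ_perp = Δ(ψ_c + π/2) obey, exactly,

    d(CR)/dt      = Δ_par  Ė (1 − C²R²),
    CR dψ_c/dt    = Δ_perp Ė,

and the principal growth direction ψ_g (where Δ is maximal) is the
direction the organ bends toward — so a fixed ψ_g attracts ψ_c
(alignment), which is the behavior the whole pattern taxonomy rests on.
The asymmetry is sometimes written with the opposite sign, with ψ_g then
marking the fast-growing flank; the two conventions differ by the
relabeling ψ_g → ψ_g + π and are kinematically indistinguishable in
every derived quantity (rates, periods, phase relationships).

**Curvature-vector state.**  The polar form above is singular at C = 0
(the 1/(CR) prefactor on dψ_c/dt).  The integrator therefore evolves the
regular curvature vector κ = CR (cos ψ_c, sin ψ_c):

    dκ/dt = ΔĖ (cos ψ_g, sin ψ_g) − (γ Ė / R) κ,

with (C, ψ_c) derived views.  Equivalence with the polar laws for C > 0
is a tested property.  ψ_c at C = 0 is undefined; the stored value (the
direction of the last nonzero κ, 0 for never-curved material) is
reported but never used in dynamics.  The quadratic (1 − C²R²) factor is
neglected by default (the CR ≪ 1 regime); a `keep_quadratic` flag
retains it on the in-plane component, in which case an aligned constant
drive follows the closed form CR(t) = tanh(ΔĖ t).

**Proprioception.**  The self-straightening term −γC added to the
in-plane differential growth becomes the isotropic damping −(γĖ/R)κ of
the curvature vector (it has no component perpendicular to κ).  Under a
uniformly rotating drive the damped system has a globally attracting
periodic orbit of amplitude |κ|* = ΔĖ / √(ω² + (γĖ/R)²).  The in-plane
proprioceptive term is implemented with the cosine projection of the
drive, consistent with the projection identities; one printed statement
of the combined law uses a sine there, which is inconsistent with those
identities and is treated as a typo.

**Material discretization and growth.**  The organ is a chain of
Lagrangian segments (default 100).  Because segments are material, the
advection term v ∂/∂s of the material derivative is realized implicitly:
after elongating each segment by (1 + Ė dt), abscissae are recomputed as
cumulative sums, which is exactly the discrete growth-displacement
integral v(s) = ∫₀ˢ Ė ds′.  Material below L − L_gz (outside a subapical
growth zone) receives Ė = 0 and therefore frozen κ.  In the
"neglect elongation" regime — used for the fixed-length pattern studies,
where elongation is a perturbation on the pattern — Ė still enters the
κ dynamics (it scales the proprioceptive damping) but rest lengths are
held constant (`elongates=False`).

**Time integration.**  Explicit Euler by default, matching the
first-order derivation of the rate equations; an optional midpoint
scheme is provided and its second-order convergence is tested against
the exact damped-rotation solution.  The simulation guard requires
dt × (fastest driver rate) ≤ 10⁻², and the auto-selected step is
min(20 s, 10⁻²/rate); at the default rates the per-step |Δκ| is ~10⁻⁵.
Internal oscillator phases (the rate-modulated rule
dψ_g/dt = ω₀(1 + a cos 2ψ_g)) are advanced with one classical RK4 step
per organ step; the closed-form full-rotation period of that rule is
2π/(ω₀√(1 − a²)).

## 3D reconstruction

Shape is recovered from (rest_length, C, ψ_c) per segment by integrating
an adapted frame (tangent t, directors d1, d2) along s: within each
segment the curvature is constant, so positions advance along an exact
circular arc toward n = cos ψ_c d1 + sin ψ_c d2 and the frame is rotated
by the exact arc rotation about t × n.  That rotation has no component
about t, so the director field is twist-free — the frame counterpart of
the modeling assumption that surface lines parallel to the axis stay
parallel (no material torsion).  Reconstruction error is therefore
purely an s-discretization effect, and zero for organs whose (C, ψ_c)
are piecewise constant on the segments.  Conventions: base clamped at
the origin, base tangent +z (opposite gravity), base director +x;
the "horizontal plane" is (x, y).  Rotating the base director is a pure
gauge: the shape rotates rigidly and all polar track quantities are
unchanged.

Surface-fiber lengths measured on the reconstructed geometry (arc angle
from consecutive tangents, bending radius from the chord) reproduce the
bent-cylinder fiber formula to machine precision — an independent
consistency check between the strain model and the reconstruction.

## Inverse estimators

*From 3D Lagrangian fields.*  Finite differences (central, away from the
time endpoints) of the per-element κ series give the drive exactly:
ψ_g = atan2(κ̇_y, κ̇_x), ΔĖ = |κ̇|; equivalently ψ_g − ψ_c =
atan2(CR ψ̇_c, d(CR)/dt).  Samples where both rate components vanish are
masked (direction undefined).

*From the horizontal tip track.*  Under the whole-organ hypotheses (the
organ is a single planar arc of uniform curvature, varying uniformly),
the tip's polar coordinates map to the organ state: ψ_c = θ and
ρ = (1 − cos CL)/C, whose small-curvature limit gives C = 2ρ/L².  Both
the exact arc inversion (Brent solve on the monotone branch, CL ≤ 2.331)
and the small-curvature proxy are exposed.  The growth direction is
estimated as the full-quadrant direction atan2(ẏ, ẋ) of the
Savitzky–Golay-smoothed tip velocity (window default: 1/10 of the
dominant period found by autocorrelation; derivative = analytic
derivative of the local polynomial; one half-window masked at each end;
samples below a speed floor of 1% of the median speed masked).  An
alternative convention arctan(dx/dy) — an angle referenced to the y axis
on a half turn — is available behind a flag for comparison with legacy
analyses; a constant reference offset cancels in every derived rate and
period.  The drive magnitude is estimated as (2R/L²)√(ẋ² + ẏ²), the
prefactor obtained by substituting C = 2ρ/L² into the exact inversion;
absolute values are therefore meaningful only when L is known, otherwise
the series is qualitative up to that prefactor.

Periods: T_r = 2π / mean rate, with the mean rate taken as total
unwrapped angle change over elapsed time between the first and last
valid samples (callers wanting unbiased means under modulated rates
should use an integer number of periods); T_o = mean time between
*alternate* maxima of dψ_g/dt, since consecutive maxima sit ~π apart in
ψ_g.  Peak detection uses a prominence floor of 25% of the series range
after Savitzky–Golay smoothing; fewer than three maxima raises a
no-signal error rather than guessing.

## Synthetic data

The track generator emulates the observed pattern classes — circle,
ellipse, line, epi-/hypotrochoid (two rotating vectors, rates ω₁ and
±6ω₁ by default) — as analytic curves with seeded isotropic Gaussian
position noise (sd expressed as a fraction of the maximal radial
excursion, emulating tracking error).  It does not emulate: torsion of
the organ (rotation of the cotyledon that would shift phase
relationships plotted against ψ_g), drift or growth of the pattern
scale within a track, heteroscedastic or correlated tracking noise, or
gaps.  Passing recovery tests on these tracks therefore shows the
estimator chain is correct under the model's own assumptions, not that
real recordings satisfy those assumptions.

## Default study conditions

Arabidopsis-like scales, chosen once: R = 0.5 mm, L0 = 20 mm, 100
segments; drive rotation ω = 4.6 × 10⁻⁴ rad/s (the scale of reported
mean growth-direction rotation rates, T_r ≈ 228 min); ΔĖ = 0.005 ω
(steady |κ|* = 0.005, i.e. CL ≈ 0.2, safely in the small-curvature
regime); Ė = 2 × 10⁻⁵ s⁻¹ (~7%/h) where elongation matters; γ set so
that the damping rate γĖ/R equals ω in the proprioception preset;
growth zone L_gz = L0/2 in the subapical preset; horizon 5 slow periods
with the first discarded from steady-state statistics; save stride 5.
Ratios fixed by the preset definitions (two-zone drive ratio 1:5, rate
ratio ±6, modulation depth a = 0.5) are kept as ratios.  Simulation
sizes throughout (10³–10⁴ steps, ~10² segments) were chosen so the whole
verification chain — unit, property and acceptance layers — runs in a
few minutes on one core.

## Known limitations

Beyond scope by design: material torsion as a growth mechanism, elastic
mechanics (self-weight, buckling), tropic responses to external stimuli,
and stochastic or circadian-gated oscillators.  The tip estimators
assume the whole-organ hypotheses; they cannot separate two superposed
zone oscillators (only an effective ψ_g is recovered, its mean-rate sign
set by the faster oscillator) and cannot distinguish median-elongation
variation from drive variation in ΔĖ since the product's sign never
changes.  The explicit Euler default trades accuracy for transparency;
the orbit-centering initial conditions and the midpoint scheme are
provided where cleaner geometry is needed.
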