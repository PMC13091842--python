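# Methods

Units are fixed package-wide: mm, N, MPa (N/mm² = MPa); moduli of the
nitinol law are stored in GPa as calibrations report them and converted
internally.  All indices are 0-based, including in CSV interchange files.

## Superelastic nitinol law

The stent material is an isothermal 1D flag model of the Auricchio family,
driven in strain.  Total strain splits into an elastic part and a
transformation part,

    eps = sigma / E(xi) + xi * eps_L * sign(sigma),

with martensite fraction `xi ∈ [0, 1]`, maximum transformation strain
`eps_L`, and the Reuss (compliance-average) mixture modulus
`E(xi) = [xi/E_M + (1-xi)/E_A]⁻¹`.  The Reuss rule was chosen over the
Voigt average because it keeps the stress–strain path consistent with the
linear plateau parameterisation.  Forward transformation moves the stress
linearly from `sigma_SL` (onset) to `sigma_EL` (finish) as `xi` goes
0 → 1; reverse transformation runs from `sigma_SU` down to `sigma_EU`.
Outside the transformation branches the response is elastic at frozen
`xi`.

The state update is an exact scalar return mapping rather than an
explicit sub-stepped integration: given the new total strain, the trial
elastic stress at frozen `xi` is compared against the current branch
stresses, and when a transformation branch is active the consistency
equation `eps = sigma_branch(xi)/E(xi) + xi*eps_L` is solved for `xi` by
bracketed root finding (the right-hand side is strictly increasing in
`xi`, so the root is unique).  This honours path dependence across calls,
locates branch boundaries exactly, and is robust under the crimp
simulator's incremental driving.  Strains carried past the martensite
finish continue on the elastic martensite branch (no failure model) and
set an `overdriven` flag on the state.

Tension–compression asymmetry: the calibrations report a single asymmetry
parameter `alpha = 0.0279` without a functional form.  The package applies
a Drucker–Prager-like onset scale `k_c = (1+alpha)/(1-alpha)` to all four
plateau stresses in compression; tension is unchanged, and `alpha = 0`
recovers a symmetric response.  This is an interpretation — other solver
conventions exist — and only affects the compressed half of a bent wire
section, where it shifts the force–diameter curve by well under the
model's overall fidelity.

Temperature effects are ignored: the calibration experiments were run at
body temperature and each device carries a single parameter set.

Packaged parameter sets (`sgmech/data/materials.json`) hold the calibrated
values for the four devices: austenite/martensite moduli 57.5/47.8 GPa
(34.5/29.8 for the ePTFE-graft device), transformation strain 0.063,
loading plateau 550→620 MPa (500→800), unloading plateau 450→250,
350→270, 350→270 and 400→200 MPa respectively, and graft moduli
1060/520/520/90 MPa.  The graft law is linear-elastic; `fit_graft_modulus`
performs the standard linearisation of a tensile curve — a least-squares
slope through the origin over strains up to 0.015 by default.

## Device geometry

Stent rings are pure sinusoids in unrolled coordinates: nodes lie on the
cylinder of the labelled diameter with
`z = axial_position + amplitude * sin(n_crowns * theta)`.  The
discretisation starts at a crown peak so that crown cells begin and end on
peaks; the default segments-per-crown targets ~1 mm beam elements.  The
published device tables give diameters, lengths, working ranges, wire and
graft thicknesses, suture spacings and stress-free diameter increases, but
not crown counts or amplitudes; the presets assume 5 crowns at 7.5 mm
amplitude for the ring-based devices (15 mm stent height) and a 12-crown,
5 mm-amplitude continuous helical sinusoid for the bonded device (10 mm
height), and these are documented as assumptions, not measured facts.
The stress-free diameter increase (ring prestress) is carried as metadata
only — geometry is built at the labelled diameter; the FEA prestressing
procedure is out of scope.  An optional straight lateral bar along one
generator supports the design with a longitudinal spine.

Connections between stent and graft are node-to-node, as in the FE models
this mirrors: suture points are sampled along each ring by arc length
(count = floor(circumference/spacing) + 1, final gap short — a
deterministic tie rule), and the chosen graft node is welded onto the
stent node position; `bonded=True` connects every covered stent node.
Collisions (two stent nodes nearest the same graft node) fall back to the
next-nearest free graft node, so connection counts are preserved and every
pair coincides exactly.

MTA ratio: strut lateral area uses the wire cylinder-surface formula
`pi * d_wire * length`, neglecting crown-curvature corrections (sub-percent
at 0.5 mm wire).  Elements crossing an axial window boundary contribute
proportionally to their axial overlap, which makes windowed MTAs over a
partition average exactly (length-weighted) to the whole-device value.

## Crimp/release simulator

A reduced-order kinematic model replaces plane-contact crimping FEA.  The
ring radius is prescribed per step.  Each crown apex is treated as a
semicircular bend whose radius scales affinely with the ring diameter,
`rho(D) = rho0 * D/D0` with `rho0 = pi*D0/(4*n_crowns)` (a quarter of the
unrolled crown wavelength) — the model's central approximation.  Fibre
strains follow beam kinematics, `eps = -y * (kappa(D) - kappa(D0))`, with
`y` the through-wire offset; the section is integrated with
Gauss–Chebyshev (second kind) nodes and chord-length weights, which sum to
the section area exactly (9 fibres by default, enough to resolve plateau
onset through the thickness).  The apex moment converts to total radial
force by virtual work over the prescribed radial mode; with `kappa ∝ 1/D`
and a semicircular apex arc this collapses to `F(D) = 2 n pi M(D) / D`.

Device curves are sums of per-ring curves at common diameter samples — no
inter-ring or graft coupling (an opt-in linear graft hoop term exists).
Both sweep branches include the turning point so that interpolation on
either branch never extrapolates.  The model reproduces the phenomenology
the metric suite needs — hysteresis with non-negative loop area that
vanishes in the elastic limit, a release branch below the loading branch,
working-range force drops — but not the absolute force magnitudes of any
commercial device, which depend on unpublished strut layouts.

Feasibility guards: the prescribed sweep must keep peak fibre strain below
the material model's 0.15 bound, and the target diameter must exceed twice
the crown amplitude.  Under the assumed 7.5 mm amplitudes this caps ring
crimps at 15 mm, so package defaults crimp to 16 mm (12 mm for the 5 mm
amplitude device); the working-range window 28–32 mm lies inside every
sweep.

Calibration is bounded least-squares over a chosen parameter subset,
re-simulating the curve per iterate and comparing branch by branch, with
configurable unloading-branch weighting (the release branch is the one
that matters clinically) and R² reported over both branches.  Invalid
parameter combinations encountered during optimisation return a large
residual rather than raising.  Self-calibration on model-generated curves
recovers planted plateau stresses to well under 2% — the package's
substitute for matching proprietary experimental curves.

## Apposition (G-APP)

G-APP is an area statement, so sampling is element-centroid based with
area weighting.  Distances are unsigned nearest distances from graft
element centroids to the wall surface: a KD-tree over wall triangle
centroids proposes candidates, an upper bound (best candidate distance
plus the largest triangle circumradius) selects every triangle that could
be nearer, and exact point-to-triangle tests decide.  The result equals
the exhaustive minimum to machine precision.  The point-triangle test
itself uses the interior-projection-or-edge decomposition, which is exact
by construction.

The threshold test is strict (`distance < 1 mm`), matching the metric's
definition as surface *lower than* 1 mm from the wall.  Sections are
half-open 1 mm bins `[s, s+1)` of centroid projections onto the
centerline arc length — binning rather than true cutting planes, which is
robust on folded grafts.  The proximal rim is the minimum projected arc
length of the covered graft; a configurable proximal offset supports
devices whose bare apexes shift the plot origin.  Window statistics are
the mean and max of section values within the first/last 10 mm; empty
bins are recorded as NaN and excluded.  By construction the per-bin
area-weighted mean of section values equals the overall G-APP exactly.

## Contact forces, NFF, SAD

Wall nodes are assigned to regions by `floor(s / 20 mm)` of their
centerline projection (half-open bins, terminal clamping with a warning
for nodes projecting beyond the polyline ends).  Per region: the nodal
|CF| distribution, its median and max, `NFF = mu * sum |CF|` with
`mu = 0.1` (an isotropic Coulomb bound on friction — no direction is
assumed), and SAD as the *fraction* of region nodes whose friction force
exceeds a tolerance (1e-6 N).  Reported SAD values in the literature are
sub-unity, implying a normalised quantity; raw contact counts are exported
alongside.  The median CF is computed over contact nodes only (sparse
contact would otherwise drive it to zero); the all-node median is also
exported.  Region NFFs sum exactly to `mu` times the global |CF| sum.

Von Mises summaries accept a precomputed scalar per node or plane-stress
components, `vm = sqrt(sxx² - sxx*syy + syy² + 3*txy²)`; the mean is
area-weighted with lumped nodal areas (one third of incident triangle
areas).  Pre/post comparisons are report-level differences of two
summaries — no FEA is performed.

## Opening areas

Crown cells are labelled at build time, one cell per crown, spanning the
sinusoid from peak to peak and closed by the chord between adjacent peaks.
Deployed struts are warped, so the opening area of a loop is defined as
the shoelace area of its projection onto its least-squares best-fit
plane: rigid-motion invariant, quadratic under uniform scaling, and
reproducible.  Collinear loops get area 0 with a warning.  Continuous-wire
frames have no closed metal circuits; their sections are taken with cut
planes normal to the axis (default one plane per crown period), each
yielding the azimuth-ordered polygon of wire crossing points.

The OA% error pairs cells by construction label, uses the reference
(segmented) frame's area as denominator, and reports absolute errors with
mean ± sd.  Sign conventions and denominators vary in the literature;
absolute/reference-denominator was chosen because the segmented
configuration plays the role of ground truth.

## Synthetic data generator

The generator produces the study conditions the metrics are exercised
under, with exact ground truth; it does not attempt mechanical realism.

*Vessels*: straight, torus-arc and linearly tapered tubes meshed as
structured triangle surfaces representing the inner lumen, with exact
centerlines.  Defaults follow the idealised testing conditions: 30 mm
diameter, 1.8 mm wall, E = 2 MPa, 80 mmHg diastolic pressure.

*Deployment* is purely kinematic — no force balance.  The graft is swept
along the centerline; at each station its radius is
`min(r_device, r_wall - gap(s))` with constant/step/tapered gap profiles.
Where the device is oversized the excess circumference folds into `k`
inward sinusoidal lobes of depth `delta`:
`r(phi) = r_base - (delta/2)(1 - cos(k*phi))`, mirroring the fold patterns
deployed grafts develop.  The wall distance is then
`gap + (delta/2)(1 - cos(k*phi))`, and the within-threshold *area*
fraction has a closed form: the angular fraction is
`arccos(1 - 2(t-gap)/delta)/pi`, and the area fraction weights it by the
circumferential arc-length element
`w(u) = sqrt(r(u)² + (delta*k/2)² sin²u)` (dense Simpson quadrature of the
exact profile; the area weighting matters — for a 3 mm, 4-lobe fold in a
30 mm tube it shifts the fraction by ~3 percentage points).  Ground-truth
records carry per-1 mm-section fractions and their area-weighted overall
value, sufficient to predict the apposition output without running it.

*Contact fields*: a seeded subset of each region's nodes receives random
positive magnitudes renormalised so the region's |CF| sum equals the
planted value exactly; directions are random unit vectors; bookkeeping
stores exact sums and counts.

*Pressure stress*: thin-wall Laplace components, hoop `p*r/t` and axial
`p*r/2t`, with 1 mmHg = 133.322 Pa — an analytic stand-in for a
vessel-prestress computation.

*Perturbed stents*: each crown cell is scaled uniformly about its loop
centroid by its own factor.  Uniform (rather than in-plane-only) scaling
keeps the best-fit plane direction invariant, so the planted OA error
`|s² - 1| * 100` is exact to machine precision; nodes shared between
adjacent cells are duplicated so per-cell scalings stay independent.  The
output frame is a synthetic stand-in for a segmented deployed stent.
Optional Gaussian coordinate noise breaks exactness and is off by default.

All generators are deterministic given their seed.

## What the tests do and do not show

The synthetic fixtures have controlled geometry: cylinders and tori with
analytic surfaces, kinematic deployments with prescribed gaps and
sinusoidal folds, planted force sums.  Passing tests therefore demonstrate
that the metric implementations are correct — exact against oracles,
invariant where they should be, and convergent under refinement — and that
the constitutive model embodies its calibrated parameters.  They do not
demonstrate that any real device achieves a particular G-APP or NFF in a
patient: those numbers depend on patient anatomy, proprietary strut
layouts and a full deployment simulation, all outside this package's
scope.

## Problem sizes and tolerances

Default problem sizes were chosen as the smallest that sit safely inside
the asymptotic regime of each check: uniaxial sweeps use 2000–4000 steps
per branch (plateau markers move < 0.5% beyond that), crimp sweeps 40–60
steps (forces converged to < 1% vs 4× refinement), vessel and graft meshes
0.5–1 mm elements (fold-fixture sectional G-APP within 0.3 percentage
points of the closed form at 0.5 mm), and the fold fixture a 60 mm tube
with a 40 mm two-ring device.  Mesh-resolution-limited comparisons use 1%
(or 1 percentage point) tolerances; oracle equivalences use 1e-9; planted
bookkeeping identities use 1e-6 or tighter.

## Known limitations

- The crimp model is phenomenological: absolute force magnitudes and
  device rankings depend on assumed crown geometry.
- The deployment surrogate has no mechanics — no recoil, no wall
  deformation, no friction during placement.
- The nitinol law is 1D; multiaxial stress states in deployed struts are
  not represented.
- Ring prestress (stress-free diameter increase) is metadata only.
- Blood flow, fatigue and temperature dependence are out of scope.
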