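# Methods

`tfm3d` measures the 3D force field that an adherent object (a resting
steel ball, a mussel plaque pulled through its thread, a cell in the
classical TFM setting) exerts on a thin elastomer substrate, from nothing
but the displacement field of the substrate surface.  This note documents
the models, numerics and design choices, and what the synthetic test
conditions do and do not establish about real measurements.

## Displacement-driven traction inversion

The substrate is a thin deformable layer (thickness `h`, default 0.3 mm)
bonded to a rigid backing.  A stereo-DIC system tracks speckle subsets on
the free surface and reports 3D displacement vectors on a regular lattice
(subset interval x pixel scale; 0.15 mm in the reference configuration).
The finite-element model of the layer is built so its top-surface nodes
coincide exactly with the subset centres: the measured vectors are applied
verbatim as Dirichlet boundary conditions (no interpolation), the bottom
surface is fully fixed, and the solved nodal reaction forces on the top
surface *are* the interfacial traction map.  Summing them gives the
resultant `RF = (RF_X, RF_Y, RF_Z)`, its magnitude, and its elevation
angle `arctan(|RF_Z| / sqrt(RF_X^2 + RF_Y^2))` above the substrate plane,
reported to 3 decimals (N) and whole degrees to match the granularity of
the tabulated stage-point results.

This is a well-posed boundary-value problem, not a regularised inverse
problem: with full-field surface data on a thin bonded layer, tractions
follow from equilibrium alone.  The price is noise amplification governed
by the substrate design model below.

## Constitutive models

The substrate (PDMS) is modelled as a two-term nearly incompressible Ogden
solid:

    W = sum_p (2 mu_p / alpha_p^2) (lb1^a_p + lb2^a_p + lb3^a_p - 3)
        + (1/D)(J - 1)^2,     lb_i = J^(-1/3) lambda_i

with initial shear modulus `G0 = sum_p mu_p` and bulk modulus `K = 2/D`;
small-strain Young's modulus and Poisson ratio follow by the isotropic
relations.  The shipped constants (`TABLE_PDMS`, `AVERAGE_PDMS` with
upper/lower batch bounds) give `G0 = 0.47--0.475 MPa`, `E = 1.25--1.43
MPa`, `nu = 0.45`.  The volumetric term `(1/D)(J-1)^2` is the lowest-order
form consistent with `K = 2/D`.

Constants are fitted to uniaxial nominal stress--strain data under
incompressible uniaxial kinematics
(`P(lam) = sum_p (2 mu_p/alpha_p)(lam^(a_p-1) - lam^(-a_p/2-1))`), by
bounded multi-start least squares (`alpha_p` in [0.1, 30], `mu_p` in
[1e-6, 10] MPa, default seed 20240101).  `D` is not fitted — uniaxial data
cannot constrain it — but set from a target Poisson ratio (default 0.45,
the value measured for PDMS).

A linear-elastic comparison model (same derived `E`, `nu`; geometrically
linear, B-bar volumetric averaging) quantifies what the hyperelastic
treatment adds: on identical boundary conditions the linear model's peak
traction falls below the Ogden model's once the peak principal stretch
deviation exceeds ~5%, and its resultant falls increasingly short as
strain grows (about -0.2% at 6% strain to -2% at 18% on the synthetic
plaque fields).

"Max principal nominal strain" is reported as `max_i |lambda_i - 1|`, the
largest principal-stretch deviation, so compression-dominated (ball) and
tension-dominated (plaque) states are measured on the same scale.

## Finite elements

Structured 8-node hexahedra with 2x2x2 Gauss quadrature; default 3 element
layers over the thickness, which together with the 0.15 mm lattice gives
~444 elements/mm^3, matching the reference model's ~475.  Near
incompressibility at `nu = 0.45` is handled with the mean-dilatation
(Q1P0) treatment.  The implementation uses the fact that the isochoric
Ogden energy is invariant under the volume-preserving rescaling of the
deformation gradient, so Q1P0 reduces exactly to: isochoric spectral
stress per Gauss point, plus a single element pressure `p = U'(Jbar)`
acting through `J F^{-T}`, plus a rank-one element tangent from
`U''(Jbar)`.  The consistent tangent is analytic (spectral formula with
the repeated-eigenvalue perturbation applied inside the tangent only;
the stress is regular there and stays exact), and Newton converges
quadratically — residual histories are asserted in the tests.

Solvers: sparse direct (SuperLU, MMD ordering).  Newton uses relative
residual 1e-8, at most 30 iterations, automatic 2x load substepping on
divergence, and a trust-region-style cap on the displacement increment
during contact solves.

Rigid-sphere contact (the validation forward problem) is node-on-
analytic-sphere frictionless penalty contact: penalty stiffness
`100 x (oedometric modulus / element height) x nodal area`, with an outer
secant iteration on the penetration depth until the summed vertical
contact force matches the target weight within 0.5%, then a final solve
at full tolerance.  Depth increments are bisected on Newton failure.
Verified insensitive to the penalty factor (x10 changes peak results
<1%) and to `nz` (3 vs 6: <1% on displacements and peak nodal force).

## Substrate design model

A bonded layer under uniform pressure responds with stiffness
`k = sigma/delta_z`.  The naive Winkler estimate `E/h` ignores lateral
confinement; the finite-thickness correction `(E/h)(1-nu^2)` is still off
by the factor `alpha(nu)`, calibrated here (as in the reference study) by
uniform-pressure FE solves on a laterally confined layer and fitted as
`alpha(nu) = -12.50 nu^2 + 6.35 nu` (quadratic through the origin,
R^2 = 1.0 at one decimal over nu in {0.30, 0.35, 0.40, 0.45}).  The
resulting `k = E / (h (1-nu^2) alpha(nu)) = (E/h) theta(nu)` reproduces
the confined-compression (oedometric) closed form
`M/h = E(1-nu)/((1+nu)(1-2nu))/h` within 2% — about 21.5 N/mm^3 at
`nu = 0.45`, `E = 1.7 MPa`, `h = 0.3 mm`, i.e. 3.8x the naive value.
(The two printed forms of the unified coefficient are mutually
inconsistent; the division convention is the one that reproduces the
calibration FE, and is adopted throughout.)

The design metrics are noise-to-deformation ratios for measurement noise
`eta` (micrometres): `psi_z = eta_z E theta/(sigma h)` for normal loading,
`psi_x = eta_x G/(t h)` for shear, and the combined bound

    psi <= (E eta_max / h) sqrt(3 / (2 (2(1+nu) t)^2 + (sigma/theta)^2)).

At the reference design point (`eta_max = 1.2 um`, `E = 1.7 MPa`,
`h = 0.3 mm`, `sigma = t = 0.05 MPa`) the bound is 5.7% — below the 10%
design target.  Note the asymmetry: theta(0.45) = 3.8 makes the
normal-only branch weak (`psi_z` alone is 52% at `sigma = 0.05 MPa`), so
the sub-10% guarantee holds for combined shear + normal loading, not for
purely normal loads.  `design_thickness` inverts the bound (it scales as
1/h) for the smallest admissible layer thickness.

## Synthetic data: what it emulates, and what it does not

Both generators produce DIC-dialect lattice fields from *forward* FE
solves, because only forward-simulated fields have exactly known discrete
resultants; every dataset ships a ground-truth sidecar (resultant, nodal
tractions, noise-free field).

* `sphere_indent`: a Ø17 mm rigid ball (20.6 g; weight 0.202 N dry,
  0.177 N net when submerged, water 1000 kg/m^3, g = 9.81 m/s^2) resting
  on the layer, frictionless.  At the wet net weight this produces a
  ~1.34 mm contact patch, 24.9 um peak normal and 8.5 um peak in-plane
  surface displacement at ~8% peak strain.
* `plaque_pull`: a shear-dominated traction distribution on a 2.8 x 2.0 mm
  elliptical footprint (paraboloid weight, zero at the rim to avoid
  mesh-dependent edge singularities), resultant at 15 degrees elevation
  toward -X, up to 0.19 N (the failure-stage load of the mussel tests,
  peak displacement ~45 um, inside the 18--47 um stage range).  Because
  the pull acts above the interface (lever arm 0.5 mm, the plaque height
  scale), the shear resultant carries a tilting moment realised as a
  linearly varying normal traction — this reproduces the observed
  tension-to-compression transition along the pull axis.  The true plaque
  traction distribution is unknown (it is what the method measures); this
  patch is a structural stand-in, not a biological claim.

Measurement noise is i.i.d. per-axis Gaussian (default up to 1.2 um std,
the filtered noise floor of the reference measurement system), seeded.

What passing the synthetic closure shows: the discretisation, mapping,
solver and bookkeeping are mutually consistent (noise-free resultants
recover to <1%, directions to <1 degree), and the noise response matches
the design model.  What it does not show: robustness to DIC artefacts that
are not i.i.d. noise (subset decorrelation, spatially correlated error,
calibration drift, surface tilt), to mask irregularities at real adhesive
rims, or to uncertainty in `h` and the material constants — on real data
those enter the error budget directly.

Noise propagation is strongly channel-asymmetric, exactly as the design
model predicts: vertical noise couples through the stiff confined-layer
response (`E theta/h`), in-plane noise only through `G/h`, an order of
magnitude softer.  Empirically the spurious resultant from pure noise
grows with the lattice window size and is *not* reduced by spatial
smoothing (smoothing removes the short-wavelength modes, which already
self-cancel in the sum, and passes the long-wavelength modes that do
not).  Consequently (i) `invert` defaults to no smoothing — gaussian and
median filters are available but help pointwise fields, not resultants —
and (ii) the 10-seed noise-robustness check runs on the shear-dominated
plaque scenario, the regime for which the sub-10% design guarantee is
stated; a purely normal load at 1.2 um noise sits outside that envelope
by the design model's own arithmetic.

## Numerical choices and edge cases

* Units: mm, N, MPa everywhere internally; noise specified in um.
* Lattice regularity enforced at 1e-4 relative; node/subset coincidence at
  1e-6 of a lattice step; masked subsets leave their nodes unconstrained.
* Repeated principal stretches: |lam_i - lam_j| < 1e-7 triggers a 1e-8
  relative split, used only in the spectral tangent.
* Element inversion during Newton triggers step backtracking (down to
  1/64 of the step), then load-increment bisection.
* Savitzky--Golay smoothing of force--extension curves defaults to window
  1501, cubic order (load-cell traces); the window clips to the largest
  valid odd length for short series.
* Sphere forward runs use a graded lateral mesh: the DIC-spacing core
  around the contact, geometric growth (x1.35) outside, out to the
  20 x 20 mm domain of the validation runs.  Problem sizes: ~7.5k elements
  for the full validation solve, ~2-5k for the test-suite scenarios.

## Known limitations

* Peak *nodal* forces are discretisation-dependent; they are comparable
  only at equal lattice spacing (maps away from 0.15 mm carry a metadata
  warning).  Against the reference FE predictions, peak displacements
  agree to a few percent while the peak nodal traction comes out ~17%
  lower; the value is mesh-converged here (stable under in-plane and
  through-thickness refinement and penalty stiffening), so the residual
  gap is attributed to element technology — the reference model used
  reduced-integration hybrid hexahedra, which concentrate the contact
  pressure slightly more than the consistently integrated Q1P0 elements
  used here.
* Frictional contact is not implemented; the dry-ball configuration
  (friction coefficient ~1.7) can only be approximated as frictionless.
* No viscoelasticity, Mullins effect or rate dependence; Ogden order <= 3.
* The inversion trusts the measured field: no regularisation, so heavy
  noise on near-normal loading propagates at the rate the design model
  predicts rather than being filtered away.
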