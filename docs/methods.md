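# Methods

## The model

`corneasim` models a thin meridian slice of the corneal stroma, in plane
strain, held at the limbus and pressurized on its posterior surface by the
intraocular pressure (IOP). The same physical picture is implemented at two
scales.

### Discrete scale

The unloaded slice is a set of N+1 concentric circular arcs (radii
R_i = R_P + i·T/N) spanning the half-aperture ±Φ*, each subdivided into
M = γN straight segments. Three families of linear springs connect the
nodes:

1. **lamellar segments** along each arc (collagen lamellae, stiffness K1),
2. **radial struts** between arcs (the hydrated proteoglycan matrix that
   keeps lamellae spaced, stiffness K2),
3. **diagonal struts** from node (i, j) to (i±1, j±1) (crosslinks and
   elastin resisting inter-lamellar sliding, stiffness K3).

Every element is stress-free in the reference state and carries the axial
force f = K(l − L). Rest lengths follow from the geometry: L2 = T/N,
L1_i = 2 R_i sin(Φ*/M), and L3² = L1_i·L1_{i+1} + L2², so one cell is an
isosceles trapezoid that flattens to a rectangle as N → ∞. The axial
stiffness K = E·A/L is independent of N because both the cross-section and
the length of an element scale as 1/N.

The IOP is a follower load on the posterior polyline. We represent it by its
conservative potential −p·D·A, where A is the signed area enclosed by the
deformed posterior polyline and the fixed chord joining its pinned
endpoints. The gradient of this potential at an interior posterior node is
exactly the textbook half-segment force
(p·D/2)(l_{j−1/2} n̂_{j−1/2} + l_{j+1/2} n̂_{j+1/2}) with n̂ the into-tissue
normal; the equivalence is unit-tested. Working with the potential keeps
the residual a true gradient, hence the Jacobian symmetric.

Equilibria solve ∇Π = 0 with Π = Σ K/2 (l − L)² − p·D·A over the free nodes
(the limbus columns j = 0, M are pinned). Everything is dimensionless
internally: lengths are divided by T, forces by K1·T, so the governing
groups are γ, Φ*, R_A/T, D/T, K2/K1, K3/K1 and p·T/K1 (1.72e-4 at baseline).

### Continuum scale

As N → ∞ at fixed γ the lattice homogenizes to an anisotropic hyperelastic
continuum on the annular sector. With κ = 2Φ*/γ, the microstructure enters
through q(R) = 1/(κR), w(R) = 1/√(1+(κR)²), and the diagonal direction
angle β(R) = arctan q, giving unit fiber directions e_R, e_Φ and
e_± = sin β e_R ± cos β e_Φ. The stored energy density is

    W = 1/(2κRD) [ (κR)² K1 (λ_Φ − 1)² + K2 (λ_R − 1)²
                   + (1 + (κR)²) K3 ((λ_+ − 1)² + (λ_− − 1)²) ]

with λ_a = √(e_a·C e_a) the stretch of direction a under the right
Cauchy–Green tensor C. The second Piola–Kirchhoff stress T = 2∂W/∂C is a sum
of rank-one fiber terms K(1 − λ_a⁻¹) e_a⊗e_a (with the κR and D factors of
the polar frame); the consistency T = 2∂W/∂C is enforced by a
finite-difference oracle test.

**Volume measure.** The energy prefactor 1/(2κRD) pairs with the measure
dV = D·R dR dΦ: counting lattice cells per unit (R, Φ) area (N²/κ of them)
and summing the per-cell spring energies reproduces the integrand
W·D·R = (1/2κ)[...] exactly. This fixes the otherwise ambiguous pairing of
prefactor and measure, and is what makes the discrete and continuum scales
agree without any fitted constant.

**Reading of the energy.** The radicand grouping is fixed by requiring that
2∂W/∂C reproduce the stress expressions containing (e·Ce)^(−1/2): the
energy must be quadratic in (λ_a − 1), not in (e·Ce − 1). This also matches
the discrete spring energy K L²/2 (λ−1)² term by term.

### Damage (keratoconus)

Disease is a prescribed stiffness loss localized at the apex:
D(Y) = Dmax(1 − (Y/Y_max)^ξ) with even ξ ≥ 2 and Y_max = R_A sin Φ* the
anterior-chord half-width (a single normalization for all layers; points
with |Y| > Y_max are clamped to zero damage with a warning). Damage scales
K1 and K3 by (1 − D); K2 is never reduced, since spacing the lamellae is its
physiological role. In the lattice, D is evaluated at each element's
reference midpoint Y; in the continuum, at quadrature points of the
reference configuration.

## Numerics

* **Discretization (continuum).** Structured bilinear elements on the
  (R, Φ) parameter rectangle, 2×2 Gauss quadrature, baseline grid 64 radial
  × 1280 azimuthal elements (azimuthal count = γ × radial count). The
  identity map is an exact discrete equilibrium at p = 0 (bilinear
  interpolation is exact for the identity on this grid).
* **Solvers.** Newton's method on the energy gradient with an analytic
  Hessian at both scales. In the continuum, the free-dof Hessian is
  assembled directly into LAPACK banded storage (the radial-fastest dof
  ordering gives half bandwidth ≈ 2(n_R+2)) and factorized with banded
  Cholesky; if the matrix is locally indefinite an escalating diagonal
  shift restores a descent direction. The factorization is reused across
  iterations and continuation steps while the residual still contracts by
  ≥5× per step (chord Newton), and refreshed otherwise — this cuts the
  baseline healthy solve from minutes to ~25 s on one core. The discrete
  lattice (≤ 42k dofs at N = 32) uses scipy's sparse LU, which is cheap at
  that size. Steps at both scales are safeguarded by backtracking line
  search on the total potential; continuum trial states with det F ≤ 0 at
  any quadrature point are rejected.
* **Continuation.** Pressure is ramped to its target in 10 equal steps
  (finite kinematics admits multiple branches; continuation keeps the
  solution on the branch connected to the stress-free reference). Damage is
  then ramped in 20 steps for Dmax ≥ 0.9 (5 otherwise). The converged state
  was verified to be independent of the path: 20 vs 100 damage steps,
  ramping pressure at full damage, and restarting from an artificially
  bulged state all return the same equilibrium.
* **Tolerances.** Residual/gradient ∞-norm ≤ 1e-10 (dimensionless) at both
  scales, max 50 Newton iterations per continuation step. This is tighter
  than strictly needed for 3-significant-figure metrics; it costs little
  because convergence is quadratic near the solution.
* **Curvature metric.** Interfaces are treated as graphs x = F(y) and the
  curvature F''/(1+F'²)^(3/2) is evaluated with 3-point centered finite
  differences on the non-uniform y grid (one-sided second-order stencils at
  the ends); the sign convention makes the unloaded cornea positive. Maxima
  exclude the outer 10% of points at each end, where the pinned limbus
  dominates. The operator reproduces 1/ρ on analytic circles to 1e-4
  relative at 200 samples and converges at second order.
* **Degenerate inputs.** Zero-length elements, non-SPD C, fold-over curves
  (non-monotone y), Dmax ≥ 1, odd M and invalid chord/radius combinations
  raise typed errors rather than propagating NaNs.

## What the package reproduces, and one disagreement

At baseline (T = 0.62 mm, R_A = 7.8 mm, D_A = 11.46 mm, γ = 20, K1 = 7.2,
K2 = 0.0072, K3 = 0.504 N/mm, p = 2 kPa) the code reproduces the published
healthy-state observables to their printed precision: Φ* ≈ 0.83 rad,
discrete maximum displacement ≈ 0.04 mm (N = 4), continuum AD = 0.04 mm,
CCT = 0.617 mm, MAC = 0.131 mm⁻¹, MPC = 0.143 mm⁻¹, against unloaded
references 0.62 mm, 0.128 mm⁻¹ and 0.139 mm⁻¹; the discrete apex
displacement converges to the continuum value as O(1/N) and the continuum
value moves by < 0.01% between 32 and 128 radial elements.

For the heavily damaged cornea (Dmax = 0.99) this implementation predicts an
anterior apex displacement of 0.82 mm at ξ = 4 (1.08 mm at ξ = 6, 0.41 mm at
ξ = 2) and a central thinning of 19.2–19.5% of the unloaded thickness,
versus the published "exceeds 1 mm" and "21–23%". We verified that our
damaged solution is grid-independent, continuation-path-independent, agrees
between the discrete and continuum scales (lattice values extrapolate to
≈0.80 mm), and is insensitive to the plausible alternative normalizations of
the damage profile; we therefore report our computed values as-is. Note that
the published ">1 mm" statement accompanies the family of damage exponents
ξ ∈ {2, 4, 6}, of which our ξ = 6 member does exceed 1 mm.

A related subtlety: in the heavily damaged state the *posterior* apex
displacement (1.01–0.90 mm across the K2 range) decreases with radial
stiffness while the anterior value increases mildly (the cornea thins less,
pushing the anterior surface out). Published sensitivity trends of "AD"
match the posterior surface for the K2 slice; both values are therefore
reported, with the anterior one as the primary AD (it is the optically
relevant surface).

## Design choices where the design was open

* **Slice depth.** Plane strain fixes the depth at one unit of length;
  it is exposed as `depth_mm` in the config (default 1 mm) since it scales
  the pressure resultant against the element stiffness.
* **Unknowns.** Cartesian nodal positions (discrete) and polar deformed
  positions (r, φ) on the (R, Φ) grid (continuum); pinned dofs are
  eliminated from the linear systems, not penalized.
* **Apex displacement** is defined on the anterior surface; the posterior
  value is carried in every report as `AD_posterior_mm`.
* **Thinning percentage** is quoted relative to the unloaded thickness
  0.62 mm (the loaded-healthy 0.617 mm alternative changes the number by
  ~0.1 percentage point; both thicknesses are in the reports).
* **Sweeps** solve every cell independently (no warm starting across
  cells): determinism and fault isolation were judged worth the modest
  extra cost at study sizes (≤ 7×7 cells, coarse grids).

## Synthetic fixtures and their limits

Tests run on generated objects only: the tiny N = 2, M = 4 lattice (15
nodes) for finite-difference oracles, manufactured deformation fields with
closed-form C for kinematics, analytic circles for the curvature operator,
and coarse continuum grids (n_R = 8–16) for property tests (monotonicity,
symmetry, determinism). These exercise the solvers under the exact
assumptions of the model — concentric unloaded arcs, uniform thickness,
linear springs, symmetric damage. Passing them says nothing about features
real corneas have and the model deliberately omits: pre-stress, 3D lamellar
architecture and interweaving, heterogeneous thickness, viscoelasticity,
asymmetric cones. Those are outside the scope of this package.

## Problem sizes

Default problem sizes are chosen so the full test suite and the
reproduction script each run in minutes on a single core: discrete lattices
up to N = 32 (M = 640, ~42k dofs), continuum grids up to 128×2560 (~660k
dofs, banded Cholesky ~1.4 GB peak). The paper-scale baseline 64×1280 grid
is used wherever a published number is checked.
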