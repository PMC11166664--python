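# Methods

## Physical model

`sacflow` simulates transient laminar flow and heat transport of blood laden
with gold and silver nanoparticles through a straight artery segment that
carries a sidewall aneurysmal sac with a ruptured apex.  Blood is treated as
a Newtonian, incompressible liquid with constant properties; the particle
suspension is dilute and uniform, so its only effect is to replace the
carrier properties by effective mixture values.

**Effective properties.**  With volume fractions φ₁ (gold) and φ₂ (silver):

- density and volumetric heat capacity by two-step volume weighting,
  e.g. ρ_hnf = (1−φ₂)[(1−φ₁)ρ_f + φ₁ρ_s1] + φ₂ρ_s2;
- dynamic viscosity by the two-step Brinkman law
  μ_hnf = μ_f/[(1−φ₁)^2.5 (1−φ₂)^2.5];
- thermal conductivity by the Maxwell dilute-sphere closure applied twice:
  gold into blood, then silver into that intermediate nanofluid.

The species order is load-bearing (the laws are not symmetric under swap)
and fixed as (gold, silver).  The bundled material table carries the study's
printed constants; the silver specific heat ships as printed
(2354 J kg⁻¹ K⁻¹) even though the handbook value is ≈235, with
`material_table(corrected_silver_cp=True)` substituting the corrected
number.  Properties are temperature independent, so the coupling is one-way:
flow drives heat, never the reverse (forced convection; no buoyancy).

**Flow.**  Incompressible Navier–Stokes with the full symmetric-gradient
viscous stress μ(∇v + ∇vᵀ), zero body force.  Two domain modes exist:

- *planar*: the 2D cut through the vessel (z axial ∈ [0, 0.7] m,
  x transverse ∈ [0, 0.09] m) carrying the sac and rupture orifice;
- *axisymmetric*: the swirl-free r–z reduction with the 1/r metric terms
  (hoop stress 2μ(u_r/r)(w_r/r), the u_r/r divergence contribution),
  integrated with the radial weight r.  Used for straight-tube verification
  only — the sidewall sac breaks axisymmetry.

**Energy.**  (ρC_p)_hnf(∂T/∂t + v·∇T) = k_hnf ∇²T + μ_hnf Φ, with Φ the
strain-rate invariant (planar: 2u_{x,x}² + 2u_{z,z}² + (u_{x,z}+u_{z,x})²;
axisymmetric adds 2(u_r/r)²).  The pressure-work term of the compressible
energy equation is excluded by default — the model is incompressible and the
source text's expansivity definition is nonstandard — but a conventional
α_p·T·(Dp/Dt) form can be switched on for experimentation.

**Boundary conditions.**  No-slip walls; a prescribed inlet speed v₀
(plug by default, retaining its wall-corner discontinuity; a parabolic
equal-mean option exists for verification); traction outlets
[−pI + μ(∇v+∇vᵀ)]n = −p̄n with p̄ = 13,000 Pa at the outlet and
p̄ = 12,990 Pa at the rupture orifice, each augmented by the standard
backflow-suppression penalty −βρ min(v·n, 0)v with β = 0.5.  All borders are
thermally insulated; the inlet carries Dirichlet T = 310 K and open
boundaries are advective (zero diffusive flux) — the compatible reading of
"all borders insulated" for open segments.  Initial state: rest, p = p_out,
T = 310 K.

### Parameters the source study does not state

The study prints the vessel size, the outlet pressure, the material table
and the mesh sizing, but not the inflow speed, the volume fractions, the sac
dimensions, or the orifice condition.  These scenario defaults are package
choices, all configurable:

| parameter | default | rationale |
| --- | --- | --- |
| v₀ | 0.08 m s⁻¹ | sits inside the reported 0.063–0.094 m s⁻¹ velocity range |
| φ₁, φ₂ | 0.01 each | representative dilute loading; a no-particle twin scenario isolates the effect |
| sac radius / neck / orifice | 0.025 / 0.035 / 0.008 m | visually matches the depicted geometry |
| sac center z | 0.30 m | as depicted, upstream of mid-vessel |
| rupture condition | traction outlet at 12,990 Pa | pressure-driven leakage; the value is the lowest reported line-graph pressure |
| T_inlet | 310 K | body temperature; matches the reported 309.99–310 K contours |

At these values Re = ρv₀H/μ ≈ 2.5×10³ — high for the laminar model, which is
retained as the study's own assumption.

## Discretization

- **Mesh**: conforming triangles.  The vessel generator seeds interior
  vertices on a hexagonal lattice thinned to a graded size field
  (h = h_min = 0.0032 m inside a ball of three orifice widths around the
  orifice, growing at (growth−1) = 0.13 per unit distance to
  h_max = 0.0169 m; arc chords additionally capped by
  curvature_factor·radius), then relaxes them by Laplacian smoothing with
  Delaunay reconnection.  Fully deterministic given the seed; element count
  at defaults ≈ 1.8×10³ (min quality ≈ 0.44 by the normalized
  4√3·area/Σl² measure, which is 1 for equilateral).  Structured
  alternating-diagonal rectangle meshes serve the verification cases.
- **Flow**: Taylor–Hood P2/P1 (inf-sup stable, no pressure stabilization to
  tune), degree-5 quadrature, direct sparse solves.  Time stepping BDF2 with
  an implicit-Euler startup step, Δt = 0.01 s.  Nonlinearity: Picard-lagged
  convection for the first iterate, then augmented with the convection
  Jacobian (Newton); plain Picard is available but contracts slowly
  (≈0.67/iteration) on the impulsive first step, whereas the default
  converges to a relative nonlinear residual of 10⁻⁸ in 2–5 iterations per
  step.  The backflow penalty is always lagged.  If no traction boundary is
  present the solver pins one pressure value and reports it (nullspace
  handling).
- **Thermal**: P1 temperature with residual-based streamline upwinding
  (SUPG): blood conductivity puts the cell Péclet number at O(10³), and the
  stabilization vanishes on exact solutions, so a uniform 310 K field is
  preserved to solver roundoff (~10⁻¹¹ K over 240 steps).  Same BDF2
  stepping, using the new-time velocity (one-way coupling).  A Courant
  advisory is logged above C = 5.

### Numerical choices and degeneracies

- Inlet plug values win over no-slip at the two inlet corners, preserving
  the discontinuous profile and making the discrete inlet flux exactly
  v₀·H.
- Dirichlet rows are imposed by row replacement; all continuity rows are
  retained, so the discrete velocity is weakly divergence-free against every
  P1 pressure function — including the constant — which makes the global
  boundary-flux balance exact up to direct-solver roundoff (observed
  ≤10⁻¹⁰ relative; the conservation check requires 10⁻⁶).
- Axisymmetric hoop terms are integrated with interior quadrature points
  (r > 0 strictly), so no axis regularization is needed; u_r = 0 is imposed
  on the axis.
- Zero-area triangles enter quality statistics as quality 0 rather than
  being dropped; inverted elements abort assembly.
- Pressure in the manufactured-solution study is compared up to its
  additive constant.

## Verification suite

Each built-in verification scenario exercises one closed form: plane
Poiseuille (u_max/U = 1.5, Δp/L = 12μU/H²), Hagen–Poiseuille in
axisymmetric mode (u_max/U = 2, Δp/L = 8μU/R², exercising the 1/r terms),
steady conduction with pinned end temperatures (linear profile), uniform
temperature invariance (≤10⁻⁹ K drift over 2.4 s), and a manufactured
solution (stream-function velocity, trigonometric pressure, sympy-derived
body force) whose observed velocity order on three uniform refinements is
≈2.97 against the formal 3.  Mechanical-energy cross-checks tie the modules
together: integrated viscous dissipation of the Poiseuille solution equals
Δp·Q within 2%, and replacing blood by the hybrid mixture rescales the
Poiseuille pressure drop by exactly μ_hnf/μ_f.

## What the rupture scenario does and does not show

The scenario is a deliberately desk-scale 2D analog of a 3D clinical-scale
simulation: ~1.8×10³ triangles instead of ~3×10⁵ elements, a parametric
circular-arc sac instead of patient anatomy, and package-chosen values for
every unreported input.  Quantities anchored to boundary data are robust to
that translation and are asserted: the domain-minimum pressure at 0.4 s
stays within 1% of the 13,000 Pa outlet level, and the maximum temperature
at 0.8 s stays within 0.01 K of 310 K (viscous heating at these scales
raises temperature by only ~10⁻⁶ K, consistent with the near-constant
reported contours).  Flow-rate-dependent quantities (the reported
0.063–0.094 m s⁻¹ velocity cells and the 13,120 Pa pressure maximum) depend
on the unreported calibration, so `compare_extremes` reports signed
relative deviations against the bundled reference table instead of
asserting equality; at the defaults the line-restricted velocity maxima
agree within 0.3–9%.  Reported "minimum velocity" cells are interpreted as
minima over the reporting midline (a domain minimum is identically zero at
no-slip walls); both domain-wide and line-restricted tables are emitted.

## Known limitations

- No turbulence or transition modeling despite Re ≈ 2.5×10³; no
  non-Newtonian rheology; rigid walls (no fluid–structure interaction).
- The 2D planar cut conserves per-unit-depth flux, not the 3D volumetric
  flux; axisymmetric mode cannot represent the sac.
- The momentum operator is unstabilized Galerkin: it is stable at the
  bundled mesh sizing, but meshes much coarser than the default (cell
  Reynolds ≳ 10³) can destabilize the transient rupture run.
- P1 temperature with SUPG is monotone only for resolved fields; sharp
  unresolved fronts overshoot at the percent level like any linear
  stabilized scheme.
- Line sampling and exports report vertex values (exact for the quadratic
  velocity at vertices); mid-edge extrema of the P2 field enter the
  domain-wide extremes but not exported point data.
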