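# Methods

## Model

The intervertebral disc is represented as a quasi-static, fiber-reinforced,
osmotically swelling continuum between rigid endplates.  Five concentric
tissue regions (nucleus pulposus NP, a one-element NP transitional ring,
inner annulus IAF, a one-element annulus transitional ring, outer annulus
OAF) share one constitutive family with region-specific constants taken from
tissue-level experiments; nothing is fitted to organ-scale outcomes.

**Matrix.**  Every region's extrafibrillar matrix is a compressible
Holmes–Mow hyperelastic solid,

    W = (λ + 2μ)/(4 β_m) · (e^Q − 1),
    Q = β_m [(2μ − λ)(I₁ − 3) + λ(I₂ − 3) − (λ + 2μ) ln J²] / (λ + 2μ),

with Lamé constants from the region's Young's modulus `E_m` and Poisson
ratio `ν`, and exponential stiffening coefficient `β_m`.  The Cauchy stress
is the exact derivative of `W` (verified against finite differences in the
test suite).

**Swelling.**  Proteoglycan fixed charges produce a Donnan osmotic pressure

    π = R T Φ (√(c_F² + c̄*²) − c̄*),     σ_Don = −π I,

where the instantaneous fixed charge density dilutes with volume change,
`c_F = φ₀w /(J − 1 + φ₀w) · c₀F`.  The external bath is 300 mOsm/L.  The
osmotic coefficient Φ = 1 and temperature T = 310 K are the ideal-Donnan /
body-temperature defaults; both are configurable.  Reference water fractions
φ₀w are not part of the published material table; the packaged defaults
(NP/NPtrans 0.80, annulus 0.70, CEP 0.60) are typical reported tissue water
contents and are configurable per region.

**Fibers.**  Annulus regions carry two fiber families at ±θ from the local
circumferential direction.  Each family has a toe-region power-law /
linear strain energy in the square stretch `I_n = λ_n²` with transition at
`I₀ = λ₀²`:

    Ψ = ξ (I_n − 1)^{β_f},   ξ = E_f (I₀ − 1)^{2−β_f} / (4 β_f (β_f − 1)),   1 ≤ I_n ≤ I₀,

zero when slack (`I_n < 1`), and above `I₀` a branch whose stress
`dΨ/dλ` is linear with slope `E_f`, offset so both energy and stress are
continuous at `λ₀` (the toe coefficient ξ is normalized so the toe-end
tangent is within a few percent of `E_f`; `Ψ₀ = E_f (I₀−1)²/(4β_f(β_f−1))`
at the transition).  Branch points belong to the toe branch (closed-interval
membership).  Buckled fibers carry no stress.

**Permeability.**  Hydraulic permeability is strain dependent,
`k = k₀ ((J − φ₀s)/(1 − φ₀s))² exp(M (J² − 1)/2)`.  All organ-scale solves
are drained (fluid-equilibrated) states, where `k` drops out; the law's
transient role is exercised by the one-dimensional consolidation engine
(below).

## Discretization and solver

Trilinear hexahedra with 2×2×2 Gauss quadrature in a total-Lagrangian
formulation.  Near-incompressible swelling response is treated with a
classical F-bar (element-mean dilatation) modification.  The element tangent
is computed by forward finite differences of the exact element internal-force
vector (24 nodal perturbations, h = 10⁻⁷ mm, vectorized over all elements),
which automatically captures the F-bar volumetric coupling; the residual
itself is exact.  Newton iteration uses sparse LU factorization, a
backtracking line search, convergence tolerance `‖r‖ ≤ tol_abs + tol_rel·S`
with `tol_rel = 10⁻⁸` against the internal-force scale `S` (the norm of the
per-dof sums of absolute element force contributions), at most 25 iterations
per solve (60 during constraint releases), and adaptive load-substep halving.
There is no randomness anywhere in the solver; identical configurations give
bit-identical results.

Constraint releases (platen conversion, the radial cut) follow an
equilibrium path: the reactions carried by the released constraints are
reapplied as external forces and ramped to zero in substeps.  The ramp is
stabilized by weak springs (5% of the median diagonal tangent stiffness)
anchored at the last converged configuration, whose stiffness ramps down
with the reactions and vanishes at full release — the final state is an
exact, unstabilized equilibrium.

## Meshes

Both the bovine cylinder and the human-like disc use one solid hexahedral
topology: a Cartesian core block mapped onto the disc by the elliptic
square-to-disc map (no axis degeneracy), surrounded by concentric element
rings, extruded axially.  The transitional layers are exactly one element
ring thick.  A radial cut seam lies along the positive x axis: the nodes on
that half-plane are duplicated and tied; the incision unties them.  The human
section is the circular topology scaled to an ellipse (left-right semi-axis
20 mm, anterior-posterior 13.4 mm, consistent with the 0.84·L_rl·L_ap ≈
900 mm² area that yields the 270 N physiological preload), height 11 mm,
with an optional initial outward bulge of the lateral boundary.

The default bovine cylinder is 20 mm diameter × 7 mm height with the nucleus
occupying half the radius (the source experiments do not publish the disc
dimensions; these defaults are configurable).  Default resolution: 24
circumferential sectors (6×6 core block), rings NP 2 / NPtrans 1 / IAF 3 /
AFtrans 1 / OAF 3, 3 axial layers — 828 elements, chosen to keep a full
two-model incision study at desk scale; the incision gaps change by only a
few percent between 288- and 828-element meshes.

## Protocols

* **Swelling.**  Models start unswollen with a stress-free mesh; fixed
  charge densities ramp 0 → full value in substeps, each solved to drained
  equilibrium.  The swelling-only model carries both fiber families from
  time zero and swells at fixed height; the multigeneration model swells
  fiber-free, optionally ramping the height by ΔH.
* **Multigenerational deposition.**  From the swollen neutral state the
  superior platen twists to −Ω; the +θ family is recorded there (deposition
  deformation gradient stored per Gauss point and at the element centroid,
  with exactly zero modulus).  Back to neutral, twist to +Ω, record the −θ
  family, return to neutral, then ramp the fiber modulus 0 → full in 10
  substeps under fixed boundary conditions.  A family's stretch is exactly 1
  at its deposition instant by construction (λ = |F F_u⁻¹ v|).
* **Preload and test cases.**  Axial preload is force-controlled through a
  bordered Newton system (the rigid platen translation is one extra
  unknown); the 12-hour hold is represented by the drained equilibrium.
  The seven organ-scale cases (slow ramp, creep, stress relaxation, axial
  compression, torsion, bending, flexion) run as sequences of drained
  equilibria with the test control as the only driven platen degree of
  freedom; rate-dependent cases are therefore reduced-fidelity and their
  curves carry `mode='drained_sequence'` metadata.
* **Incision.**  The validation experiment cuts discs that have been
  removed from their endplates, so before the cut the platens are converted
  to rigid frictionless supports (in-plane reactions ramped to zero) and the
  superior platen is driven to zero net axial force.  End surfaces remain
  planar — the well-conditioned stand-in for full detachment (a fully
  free-floating release is available as an option, but it traverses
  nearly-unconstrained soft modes — the inner annulus sits near J ≈ 0.7
  under swelling, wrinkling territory — where Newton convergence is
  unreliable).  The cut ties are then released along the ramped-reaction
  path and the opening gap measured between the cut-face outer edges at
  mid-height.  The measurement locus is a package choice (the experimental
  definition is not published); the inner edge is available as an option.

## One-dimensional consolidation

The transient biphasic demonstrator is a confined column (impermeable fixed
bottom, free-draining loaded top) discretized with linear displacement and
pressure elements and stepped by backward Euler with a geometrically growing
time step (`dt ≤ 0.05 t`), Newton-solving the coupled nonlinear system each
step.  In the small-strain, constant-permeability limit it reproduces
Terzaghi's analytic series to better than 1% of the final settlement at 20
time points spanning two consolidation time constants, and at any load it
converges to the drained elastic equilibrium (verified against a scalar
root-find).

## Synthetic fixtures

Experimental organ-scale curves from the cited validation studies are not
redistributable.  The fixtures module generates deterministic synthetic
stand-ins (power-law-plus-linear ramps, saturating-exponential creep and
relaxation, symmetric CI bands, optional seeded noise) used by the NMSE
machinery and its tests.  Passing NMSE tests therefore demonstrates the
metric and plumbing, not agreement with real experimental data.  All
randomness in the package is confined to these fixtures behind an explicit
seed.

## What the tests do and do not show

The synthetic-data path exercises every constitutive equation, the
multigeneration bookkeeping, and the full protocol engine at desk scale
(coarse meshes, hundreds to ~1000 elements).  The qualitative claims —
swelling-only gap exceeding the multigeneration gap, torsional stiffening
with deposition twist, more uniform multigeneration fiber strain — are
mesh-robust mechanisms.  Quantitative gap values depend on the assumed
bovine geometry, the water fractions, and mesh resolution; they are
reproduced at the package's default study conditions, not at the original
model's (unpublished) production scale.  Known limitations: no transient
biphasic organ-scale response (drained equilibria only), no contact, no
CEP layers in the default meshes, no regional (circumferential) material
variation, rigid platens instead of deformable vertebral bodies (the
compressible Neo-Hookean law for compliant platens is provided but unused
by default).
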