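# Methods

## The model

The simulator couples two descriptions of a tethered, cell-seeded collagen
construct:

**Tissue scale.** The gel occupies a cuboid Ω = [0, Lx] × [0, Ly] × [0, Lz]
(default 30 × 20 × 12 mm, the culture-chamber size) and is modelled as an
isotropic linear-elastic solid: elastic modulus E = 100 kPa, Poisson ratio
ν = 0.45 (near-incompressible, the gel being ~99 % water), density
ρ = 1100 kg m⁻³.  Density is stored for completeness only — the solves are
quasi-static and inertia never enters.  The two x-extreme faces are fixed in
all three components, mimicking the anchor bars of the culture chamber; all
other surfaces are traction-free.  The domain is meshed into cubic 8-node
trilinear hexahedra (default edge h = 1 mm → 7200 elements, 8463 nodes,
25 389 DOF).

**Cell scale.** The seeded cells are agents: particles with a position
(tracked in the material frame) and an axial orientation **v** (a unit
vector with **v** ≡ −**v**).  An agent stands for `cells_per_agent` real
cells (default 100, so the default population is 60 000 agents for
6 × 10⁶ cells) and carries their summed contractile force; total
contractility is independent of the representation ratio.  Cells obey two
rules and nothing else — no proliferation, death, or active migration:

1. *Contraction*: each cell exerts a force dipole of magnitude
   F = 1.0 nN along its axis.  The default is the midpoint of the
   0.1–10 nN range reported for single cells in collagen matrices by
   culture-force-monitor style experiments.
2. *Strain-following reorientation*: each coupling step, a cell adopts the
   principal direction of the local strain of the construct's accumulated
   deformation (details below).

**Coupling loop.** Every timestep Δt (default 1 h) for a duration T
(default 7 days → 168 steps):

1. the dipole tensors of the cells in each element are integrated into one
   element-level active stress
   σ\*ₑ = (1/Vₑ) Σ_cells F d (**v** ⊗ **v**), with coupling length d equal
   to the element size;
2. equivalent nodal loads f = −∫ B̄ᵀ σ\* dV are assembled and the
   quasi-static equilibrium K u = f is solved on the current geometry with
   the end faces clamped;
3. the strain of the total accumulated displacement is recovered at element
   centroids and its principal decomposition provides each element's
   guidance direction;
4. agents reorient (instantaneously and completely) to their element's
   guidance axis; elements with degenerate principal values give no cue and
   their agents keep their orientation;
5. with the geometry update enabled (default), node coordinates are
   incremented by the solved displacements and agents advect exactly with
   the material; the next step's equilibrium is solved on the deformed
   geometry (updated-Lagrangian accumulation).  No stress or strain is
   remembered between steps: permanence of contraction is carried entirely
   by the geometry.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `extents` | (0.030, 0.020, 0.012) | m | construct dimensions; x is the long (anchored) axis |
| `element_size` | 0.001 | m | hexahedron edge; also the cell-coupling length d |
| `elastic_modulus` | 100e3 | Pa | gel stiffness |
| `poisson_ratio` | 0.45 | – | near-incompressibility; ≥ 0.5 rejected |
| `total_cells` | 6e6 | – | seeded population (alternative: seeding density × volume) |
| `cells_per_agent` | 100 | – | representation ratio (fidelity/cost knob) |
| `force_per_cell` | 1.0e-9 | N | contractile dipole magnitude per cell |
| `timestep`, `duration` | 3600, 7 days | s | coupling cadence and horizon |
| `geometry_update` | on | – | updated-Lagrangian accumulation |
| `guidance_mode` | `tensile` | – | eigenpair used as the cue (see below) |
| `load_mode` | `element` | – | cube-aggregated active stress vs per-agent dipole endpoints |
| `seed` | required | – | sole source of randomness (initial positions/orientations) |

The cell count is quoted in two inconsistent ways for this construct in the
source experiments — six million cells total, and a seeding density of
5 × 10⁶ cells/cm³ (which over 7.2 mL is 3.6 × 10⁷).  The configuration
accepts either (`total_cells` xor `seeding_density_per_cm3`) and defaults to
the six-million total; the discrepancy is surfaced, not resolved.

## Numerical choices

- **Element formulation.** Full 2×2×2 Gauss integration with a
  mean-dilatation (B̄) projection of the volumetric strain.  At ν = 0.45 a
  fully integrated trilinear brick locks volumetrically; the B̄ projection
  removes that spurious stiffness while leaving constant-strain states
  exact, so the patch test passes to machine precision.
- **Strain recovery** at the element centroid from the compatible
  strain-displacement operator — one tensor per cube, the granularity of
  the cell coupling.
- **Guidance eigenpair.** The cue is the eigenvector of the *algebraically
  largest* principal strain (`tensile`).  In a gel contracting between
  fixed ends, axial shortening is blocked while the free lateral faces
  contract, so the least-compressive direction runs along the long axis —
  the direction of relative tension, which is what aligning cells follow.
  The alternative `magnitude` mode (largest-|λ| eigenpair) selects the
  dominant lateral *compression* in this geometry and drives transverse
  alignment, contrary to the observed longitudinal morphology; it is kept
  as an option for comparison.  Degeneracy (zero strain, or a relative
  eigenvalue gap below 10⁻⁶) suppresses the cue.  Eigenvector signs are
  fixed deterministically (first component above 10⁻¹⁰ made positive);
  orientations are axes, so the sign never matters physically.
- **Cumulative rather than incremental guidance.** Cells follow the strain
  of the *total* deformation since day 0, not the last hourly increment.
  The incremental field is self-defeating: once the population aligns
  axially between fixed ends, its own incremental strain collapses to
  numerical noise (axial contraction is blocked and the transverse active
  stress vanishes with alignment), and an increment-guided population
  disorders itself again.  The accumulated field retains the frozen-in
  lateral contraction and is the construct's actual strain state.
- **Load assembly.** Default `element` mode integrates the cell dipoles of
  each cube into one element active stress before assembly — the force
  within a unit cube is what the tissue model sees.  The alternative
  `dipole` mode splats each agent's two endpoint forces (position ± d/2
  along **v**, trilinear weights, endpoints clamped to the surface)
  directly onto its element's nodes; it is retained for comparison but
  injects the near-field of every point dipole into the centroid strain
  samples, a discreteness noise that does not shrink with agent count and
  measurably degrades alignment.  Both modes conserve momentum to
  round-off by construction.
- **Solver.** Sparse Cholesky-like direct factorisation (SuperLU, COLAMD
  ordering) of the constrained operator.  The operator, its factor and the
  load-integration tensors are lagged: they are rebuilt only when some node
  has drifted more than `reassembly_drift` (default 10⁻³) element lengths
  from the geometry they were assembled on — a modified-Newton style
  approximation whose geometric error is bounded by the drift threshold.
  At the nominal contractility a 168-step run performs a handful of
  factorisations; each hourly solve is then a single triangular solve.
- **Agent bookkeeping in the material frame.** Because agents advect
  exactly with the gel, their material coordinates are constants of the
  run; element lookup is closed-form on the structured reference grid
  (ties on shared faces resolved to the lower-index element) and spatial
  positions are obtained isoparametrically from the current geometry.
- **Footprint area** is the exact polygon union (shapely) of the deformed
  top-surface faces projected on the x–y plane — the top view.  The
  percent change is 100 (A₀ − A_t)/A₀, positive for contraction.
- **Order parameter** is ⟨cos²θ⟩ about the long axis — the nematic order
  parameter S = (3⟨cos²θ⟩ − 1)/2 rescaled to [0, 1]; isotropic baseline
  1/3.  It is invariant under sign flips of any orientations.

## What the simulator does and does not emulate

The simulator is its own data source: the initial condition (uniform random
positions, isotropic axial orientations) is the seeded gel at day 0, and
every reported number is computed, not fitted.  The model reproduces, with
the nominal parameters, the *direction* and *pattern* of construct
development: inward bowing concentrated at mid-length, longitudinal
alignment emerging within the first simulated day (order parameter ≈ 0.75
at day 1 against the 1/3 baseline, ≈ 0.84 in the mid-construct by day 4),
and weaker, more off-axis ordering near the clamps.

It does not reproduce the *magnitude* of experimental contraction at those
parameters, and cannot: the entire mechanical drive is the population's
contractile stress σ\* = n F d ≈ 8 × 10¹¹ m⁻³ × 10⁻⁹ N × 10⁻³ m ≈ 0.8 Pa,
against a matrix modulus of 10⁵ Pa.  Linearity makes the response scale
with the single ratio σ\*/E ≈ 10⁻⁵ (verified numerically in
`examples/contractility_sweep.py`: day-7 footprint loss 0.0017 % → 0.17 %
→ 2.4 % as the per-cell force is scaled ×1, ×100, ×1000), so a week of
hourly accumulation changes the footprint by ~1.4 × 10⁻³ % — four orders
below the tens-of-percent contraction of real tethered gels.  Reaching the
experimental regime within this model requires a contractility-to-stiffness
ratio several orders larger than the nominal values imply; physically,
reconstituted collagen hydrogels measure hundreds of Pa rather than
100 kPa, real per-cell tractions reach tens of nN, and real gels compact
plastically (volume loss), none of which linear elasticity at the nominal
constants provides.  The package deliberately keeps the nominal defaults
and exposes the discrepancy rather than hiding a calibration inside.

Two related qualitative caveats at small strain:

- An axially aligned population between two fully clamped faces is in
  equilibrium at *zero* strain (uniform axial active stress satisfies
  equilibrium with traction-free lateral faces), so sustained contraction
  requires the transverse component of incomplete alignment; tests of
  monotone contraction therefore maintain a transverse drive.
- The clamped faces *concentrate* strain in their corner elements (clamp
  singularity) rather than shielding them; the classic low-strain shielded
  corner appears only once bulk deformation is large enough to dominate
  the clamp concentration, i.e. again only at large σ\*/E.

## Known limitations

Linear kinematics per step with explicit geometry accumulation (no finite
strain measure, no remeshing — elements are checked for inversion and the
run aborts with the element index); no viscoelasticity, plastic compaction
or fluid loss; no biochemical coupling (oxygen, nutrients, ECM turnover);
no cell–cell mechanics, proliferation or death; instantaneous reorientation
kinetics.  The representative-agent ratio trades granularity noise against
cost: per-element agent counts fluctuate (Poisson), which perturbs the
guidance field; the default 100:1 ratio leaves mid-construct day-1 order
around 0.79 where a finer representation (and the full 6 × 10⁶ individuals)
would order slightly higher.
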