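# Methods

This note documents the models, parameter choices and numerical decisions
behind rhinoflow, and what the shipped phantom studies do and do not
demonstrate.

## Problem statement

Obstructed nasal breathing is usually caused by local constrictions of the
nasal airway (e.g. a deviated septum). Clinical pressure/flow measurements
(rhinomanometry) quantify the total resistance between nostril and
nasopharynx but not *where* the resistance arises. The pipeline localizes
constrictions from simulated airflow, then performs *virtual surgery*:
it widens the airway at those locations until a criterion of healthy flow
is met, and reports the widened volume as the suggested tissue resection.

## Flow model

**Lattice:** D3Q19, single-relaxation-time (BGK) collision, populations in
float64 stored sparsely on fluid voxels with precomputed streaming index
tables (cost per step ∝ fluid voxels). D3Q19 violates full rotational
invariance; the test suite asserts the axis-permutation symmetry that the
stencil does have.

**Turbulence closure:** Smagorinsky large-eddy model with constant
c_s = 0.14 and filter width of one lattice spacing. The effective
relaxation time is computed per voxel from the non-equilibrium momentum
flux Π: τ = (τ₀ + √(τ₀² + 18√2·c_s²·|Π|/ρ))/2, which adds a local eddy
viscosity proportional to the resolved strain rate. This both models
transitional flow features and stabilizes the solver when τ₀ is close to
its lower limit of 1/2.

**Boundary conditions:**

* *Walls* — halfway bounce-back (no-slip plane half a voxel beyond the
  last fluid node). This is a deliberate simplification of more elaborate
  wall models; at phantom scale the first-order wall-placement difference
  is immaterial, and bounce-back conserves mass exactly.
* *Outlet* (nasopharynx cuboid surface) — velocity Dirichlet: populations
  on surface voxels that expose at least one face to the airway are set to
  equilibrium at the local density and a prescribed suction velocity
  u = −(Q_lat/N_faces)·n̂_sum, where n̂_sum sums the exposed unit face
  normals. This makes the *discrete* face flux equal the configured flow
  rate under the equilibrium approximation; the flux actually realized in
  a simulation is within roughly 20% of nominal at desk resolution (the
  non-equilibrium part of the populations is not controlled). The
  effective rate is whatever the Δp trace was measured at, and it is the
  same in the pre- and post-surgery runs being compared.
* *Inlet* (nostril sphere surface) — ambient pressure: equilibrium at the
  reference density with the local velocity, i.e. an open reservoir of
  still air.
* *Plenum* — cuboid-interior voxels behind the outlet surface are relaxed
  to the reference density each step, absorbing the inhaled mass. Without
  this sink the closed cuboid would pressurize.

**Unit mapping:** Δx equals the voxel spacing. Δt is the largest value
satisfying (a) peak expected lattice velocity = flow rate / smallest
airway cross-section ≤ 0.1 (compressibility-error cap) and (b)
τ₀ = 3·ν_phys·Δt/Δx² + 0.5 ≤ 1.99. Pressure conversion:
p = (ρ_lat − 1)·(1/3)·(Δx/Δt)²·ρ_air. Air: ν = 1.5×10⁻⁵ m²/s,
ρ = 1.2 kg/m³.

A numerical detail worth recording: the rest weight of the stencil is
nudged by one unit in the last place so that the numpy reduction used for
the density sums the 19 weights to exactly 1.0. The uniform state at rest
is then a *bitwise* fixed point of collide–stream, and closed-box mass is
conserved to ~10⁻¹³ relative over 1000 steps (both are asserted).

**Developed-flow criterion:** a run is flagged developed when the
inlet–outlet pressure-drop trace varies by less than `convergence_tol`
(default 5%) over the last 10% of steps.

**Mean fields:** the streamline analysis consumes velocity and pressure
fields *time-averaged over the last 20% of steps* rather than the final
instantaneous state. The instantaneous LES field carries acoustic startup
waves and, at higher Reynolds numbers, turbulent fluctuations whose local
pressure gradients are not obstruction features; the mean field is the
quantity the gradient criterion is meant to probe.

## Streamlines and HPGRs

Streamlines solve dx/ds = v/|v| (arc length s in mm) with adaptive RK45
(relative tolerance 10⁻⁴, absolute 10⁻³ mm, max step 5 voxels) and
trilinear velocity interpolation; integration direction "both" joins a
backward and a forward branch through the seed. Branches stop at the
domain boundary, at a stagnation floor of |v| < 10⁻⁶ m/s, or at the
maximum length (default 300 mm, far beyond any airway). Vertices are
resampled uniformly at half a voxel of arc, so per-segment pressure
differences give dp/dl in Pa/mm directly. Seeds are uniform in the inlet
sphere (rejection-sampled against the fluid mask), 532 by default.

An HPGR is a segment with dp/dl ≤ threshold (and strictly negative: a
flat segment is never an HPGR, which keeps the sweep well-defined at its
0 Pa/mm endpoint). Detections are deduplicated to one per occupied voxel
bin (default bin: 2× lattice spacing; the desk config uses 1 mm), keeping
the steepest segment as representative; counts are therefore robust to
seed density and vertex spacing. The shipped decision rule is ≥ 25 bins
at −1.1 Pa/mm, inclusive at the boundary. Segments inside (a 2 mm
dilation of) the inlet sphere and outlet cuboid are excluded: those bodies
are artificial boundary constructs and optimizing against gradients there
destabilizes the solver.

The sweep curve (counts over thresholds −5 … 0 Pa/mm in 0.1 steps) is
non-increasing toward more negative thresholds on any input, and
`coverage_study` reports covered bins versus seed count with prefix-nested
seed sets (monotone by construction) to justify a seed budget.

## Virtual surgery

Each selected HPGR founds an optimization cube (OC, 10 mm side, HPGR at
the centre; clipped at volume bounds with a warning) and a region of
interest initially equal to the OC. Per iteration:

1. Inside each ROI the discrete Laplacian of the fluid mask marks the
   fluid–solid edge; edge solid voxels whose supporting fluid neighbour
   lies on the OC-centre side are converted to fluid (one layer per
   iteration — the wall moves in the surface-normal direction away from
   the airway). An all-edge dilation mode is available as a fallback.
   Voxels within the inlet/outlet exclusion zone are never converted.
2. Every ROI grows by 0.234 mm per face, i.e. 0.468 mm per axis — the two
   common phrasings of the growth step (per-face and per-axis) are
   consistent under this reading, and both are honoured simultaneously.
3. The flow is re-solved for the short duration (default 0.00625 s),
   warm-started from the *initial* solution with new voxels at rest. Warm
   starting from the initial solution rather than the previous iterate is
   unusual but deliberate: it makes every iteration's flow state a pure
   function of the current geometry and the initial solution, so iterations
   cannot accumulate transient bias (a config switch selects the previous
   iterate instead).
4. Streamlines and HPGRs are recomputed (same seeds); HPGRs inside ROIs
   are kept. A new HPGR inside a ROI that is not already covered by an OC
   founds a supplementary OC/ROI pair (existing ones persist).

The loop stops when the *total* HPGR count across ROIs falls below 5
(read as "fewer than 5 in all ROIs combined"), or at `max_iterations`
(default 30, reported as non-converged). The resection mask is exactly
final fluid ∖ initial fluid — monotone growth is enforced, and the
bookkeeping identity |resection|·Δx³ = (final − initial fluid counts)·Δx³
is asserted at every iteration.

HPGRs selected inside the exclusion zone are rejected up front with an
explanatory error (optimization next to the artificial bodies diverges).

## Verification and outcome metrics

* **GCI** — observed order p = ln((f₃−f₂)/(f₂−f₁))/ln r, Richardson
  extrapolate f₀, indices gci_ij = 1.25·|(f_j−f_i)/f_i|/(r^p − 1) with
  Roache's safety factor 1.25 for three-grid studies, and the
  mesh-independence ratio MI = gci₂₃/(r^p·gci₁₂) ≈ 1 in the asymptotic
  range. Oscillatory series are rejected explicitly.
* **ΔΠ** = (Δp_pre − Δp_virtual)/(Δp_pre − Δp_post), signed; 1 means the
  virtual plan predicted the achieved pressure change exactly. Invariant
  under affine rescaling of all three pressures (property-tested).
* **A(d)** — per-slice cross-section area along a chosen axis with
  exclusion masks (boundary bodies, sinuses), and **ΔA** = A_virtual /
  A_post at an investigation plane.

## The phantom study conditions

The phantom generator rasterizes circular channels by voxel-centre
inclusion (no anti-aliasing), so segmentation targets are exactly
countable; a raised-cosine radius profile forms the stenosis and a
half-sine lateral bow the septum-like deviation; two-channel phantoms
merge via overlapping cylinders (flow topology, not anatomy). HU values
−1000/+40 straddle the −300 threshold with a wide margin.

The shipped desk study is a 96×64×64 voxel volume at 0.5 mm: a 48 mm
channel of radius 6 mm with a 50% stenosis (12 mm wide, centred at
24 mm), a 20 mm inlet sphere and a 10×16×16 mm outlet cuboid. The flow
rate is 60 ml/s, not the clinical 600 ml/s: at this scale 600 ml/s would
put the throat jet deep into the turbulent regime (Re ≈ 2400 was tried
during development and floods the domain with fluctuation gradients that a
0.5 mm lattice cannot average away within the short run), whereas 60 ml/s
gives a steady laminar throat flow at Re ≈ 850 with an unambiguous
obstruction signal — the regime in which the pipeline's regression
properties are well defined. All analysis constants (−1.1 Pa/mm, 25
bins, 532 seeds, 10 mm OC, 0.468 mm growth, stop < 5, 0.0125/0.00625 s)
are the clinical defaults. Typical problem sizes: ≈ 58 000 fluid voxels,
≈ 540 steps for the initial run, one to a few surgery iterations; the
miniature test config (48×28×28 at 1 mm, 96 seeds) exercises the same
code paths in seconds.

What the phantom passes do **not** show: performance on real anatomy
(thin meatus, sinuses, mucosal texture), behaviour of the criterion at
clinical Reynolds numbers, or clinical validity of the suggested
resections. The per-case pressure and area tables that the metric functions are
exercised against are reference simulation results used as fixed inputs,
not quantities this package recomputes from CT data.

## Known limitations

* The realized outlet flow rate tracks the nominal one only to ~20% at
  desk resolution (equilibrium outflow approximation); comparisons
  (pre vs virtual) are at matched settings, so ratios are unaffected.
* Halfway bounce-back places walls to first order; no turbulent wall
  model.
* Single-relaxation-time collision; no D3Q27/MRT option.
* The optimizer has no anatomical constraints — it will happily resect
  through structures a surgeon would preserve; ROIs near the artificial
  inlet/outlet are refused rather than handled.
* Exhalation, the nasal cycle, heat/humidity transport and mucosal
  physiology are out of scope.
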