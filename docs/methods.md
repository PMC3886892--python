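# Methods

`dimerpmf` reconstructs orientation-resolved free-energy landscapes for the
lateral association of two rigid membrane-protein bodies in a lipid layer,
and analyses the lipid-packing origin of the metastable structure in those
landscapes.  This note records the model, the estimators, the numerical
choices and their rationale, and what the built-in synthetic system does
and does not demonstrate.

## The toy membrane

Real coarse-grained bilayer trajectories of this kind are cluster-scale and
not redistributable, so the package ships a quasi-2D toy membrane whose
*statistical* structure matches what the analysis pipeline needs: thermal
motion at fixed temperature, short-range lipid packing that produces
annular density shells around embedded bodies, harmonic centre-of-mass
umbrella biases, and torque-only orientational restraints.

All quantities are in dimensionless toy units: the lipid disc diameter σ is
the length unit, k_BT at `temperature = 1` the energy unit, the lipid
friction γ the time scale (τ = σ²γ/k_BT).  A bookkeeping factor
`nm_per_unit = 0.47` is recorded in output headers so downstream files are
self-describing; it is not a physical claim.

Components and interactions:

* **Lipids** — one disc per lipid, purely repulsive harmonic soft core
  `U(r) = ε/2 (1 − r/σ)²` for `r < σ` with `ε = 200`.  At T = 1 this gives
  an effective hard diameter ≈ 0.93 σ — hard enough for packing shells —
  while admitting a five-fold larger stable timestep than a truncated 12-6
  core.  A `leaflet` tag (alternating upper/lower) is carried per lipid
  purely as an analysis channel; both leaflets live in the same plane.
* **Proteins** — rigid rings of `n_body_particles = 28` particles spaced at
  equal *arc length* on an ellipse with semi-axes (2.0, 1.2) σ.  Equal-arc
  spacing matters: equal-parameter spacing crowds particles at the
  high-curvature narrow tips and biases every contact interaction toward
  them.  Ring particles repel lipids and the other body's ring with the
  same soft core (mixing diameters (σ_ring + σ)/2 and σ_ring, with
  σ_ring = 0.6).
* **Protein–protein cohesion** — rings of *different* bodies additionally
  attract through a short-range Gaussian well of depth
  `protein_attraction = 0.5` and range 0.3 centred at ring-particle
  contact.  This is the toy's stand-in for the net coarse-grained
  protein–protein affinity; it is what creates a contact well whose depth
  grows with the extent of the protein–protein interface, which is the
  orientation-dependence the buried-area analysis quantifies.  Without it
  the landscape is purely the (oscillatory, net-repulsive at this density)
  lipid-packing free energy.
* **Dynamics** — overdamped (first-order) Langevin:
  `x ← x + (Δt/γ) F + √(2 T Δt/γ) ξ`, the cheapest dynamics whose
  stationary distribution is Boltzmann, which is all WHAM requires.
  Proteins move as rigid bodies: ring forces are reduced to a COM force and
  a torque, with their own friction constants (`com_friction = 6`,
  `rot_friction = 20`) chosen smaller than the sum of per-particle
  frictions to decorrelate the reaction coordinate faster; mobilities are
  free parameters of an overdamped toy, not physical predictions.
  Timestep `5·10⁻⁴ τ` (max per-step drift ≲ 0.05 σ at the steepest
  admissible overlap).  Periodic square box (side 16 σ), minimum-image
  convention everywhere; coordinates are stored unwrapped so diffusion
  observables stay meaningful.
* **Initialization** — lipids on a jittered lattice (spacing ≥ 0.85 σ,
  bounded retries, error if the density is unplaceable) excluding the
  protein interiors plus one interaction margin.  `n_lipids = 190` in the
  16 σ box gives an effective packing fraction ≈ 0.55, dense enough for
  two to three visible shells.

## Restraints

* **Umbrella bias** `E = k/2 (d − d₀)²` on the minimum-image inter-COM
  separation d, apportioned equally and oppositely to the two bodies.
* **Transverse restraint.**  The windows restrain the bodies at *relative
  positions*, not merely at a scalar distance: a harmonic restraint
  (`transverse_restraint = 10`) on the off-axis component of the COM
  difference keeps the approach collinear.  Without it a compressed window
  escapes sideways (e.g. a narrow–narrow pair slides into broadside
  contact), disconnecting the sampled support and mixing contact
  geometries.  It is identical in every window of a configuration, so it
  defines the pathway rather than biasing the reaction coordinate; only the
  umbrella term is unbiased by WHAM.
* **Rotational restraint** — a pivot-free, torque-only potential

      E = (k_rot/2) Σᵢ [sᵢ · (xᵢ − x_c)]²,
      sᵢ = (v × ρᵢ)/√(|ρᵢ|² + ε′),  ρᵢ = Ω(yᵢ − y_c),

  penalizing displacement along the tangent of each particle's reference
  radius.  Because it depends only on COM-relative positions, the forces
  sum to zero exactly; the resultant is a pure torque about the COM along
  ±v, and per-particle forces are exactly tangential to the reference radii
  (radial forces are "virtually eliminated": the leakage onto the current
  radii is first order in the angular displacement).  For a rigid body the
  potential collapses to `E(φ) = κ_eff/2 sin²φ` with
  `κ_eff = k_rot Σ |ρᵢ|⁴/(|ρᵢ|² + ε′)`, which is how the integrator applies
  it.  Defaults `k_rot = 50` (κ_eff ≈ 3.8·10³ k_BT/rad², thermal drift
  ≈ 0.9° RMS — comfortably below a degree of typical drift) and
  `ε′ = 10⁻⁴`; Ω is the identity (orientations are held, not driven).
  Orientation angles are reported in degrees, counter-clockwise viewed from
  the declared extracellular side, measured from the inter-COM line;
  0° means the wide face points at the partner.

## Window placement and the lipidation problem

Umbrella windows: a coarse grid (2.6–7.0 σ, 0.2 σ spacing, k = 30) outside
the contact zone, plus a finer, stiffer grid (k = 200) spanning
contact−0.2 σ to contact+2.4 σ — 0.05 σ spacing across the steep contact
flank (where the mean force shifts each biased distribution by more than
one window spacing) and 0.1 σ beyond it — where "contact" is the smallest
non-overlapping collinear separation computed per orientation.  Windows
whose centre lies more than 0.5 σ below contact are dropped (they only
press into the repulsive wall), and coarse windows inside the fine grid's
span are dropped as redundant.  Each window runs 19 200 production steps
after 3 000 equilibration steps and records 1 600 reaction-coordinate
samples (every 12 steps).

Lipid exchange at the closing interface is the slowest process in the
system: a window started with an empty interface rarely acquires its
equilibrium lipid occupancy within the run, and vice versa.  The recipe
therefore pools, into the same WHAM solve, additional stiff windows
(contact+0.4 … contact+2.0 σ, 0.2 σ spacing) initialized with a lipid
seeded at the interface midpoint, alongside the standard windows whose
initialization leaves the closing gap empty.  Each window's initialization
state is preserved in a provenance flag.  A `delipidated` initialization
(interface slab actively cleared) is also available.

## WHAM

Standard self-consistent binned WHAM in log space (`logsumexp`), bin width
0.05 σ for toy landscapes (0.02 in the 1D oracle fixtures), convergence
when no window shift f_k changes by more than 10⁻⁶ energy units between
iterations.  The sampled support is the contiguous occupied island of bins
carrying the most counts; stray isolated bins (a few tail samples beyond an
empty bin) are reported as gaps with no free energy — free energies are
never interpolated or invented — while a second island with substantial
weight (≥ max(0.5 % of samples, 8)) raises a disconnected-support error
naming the gap.  PMFs are zero-referenced at 7.0 σ, where the toy profile
has become flat to within noise.  The only statistical error estimate is
the split-half discrepancy: two complete WHAM solves on the contiguous
first and second halves of every window's series, identically referenced,
compared pointwise on common support.  No autocorrelation weighting, MBAR
generalization or bootstrap.

Note the reaction coordinate is a planar distance, so the raw PMF contains
a −T ln d entropic term (≈ 0.4 k_BT of tilt between 4.5 and 7 σ at these
scales); it is common to both halves of every comparison made here and is
left in, matching the referencing convention of setting the PMF to zero
where it flattens.

## Landscape anatomy

Discrete local minima (strictly below both neighbours) are filtered by
prominence (default 0.25 k_BT — below the shallowest metastable features of
interest, above counting ripple) and refined by least-squares parabolas
over ±2 bins, giving sub-bin vertex locations; fits with non-positive
curvature or runaway vertices are rejected, and each record reports how far
the vertex moves when the window grows or shrinks by one bin.  Well depth
is the deepest fitted vertex ordinate relative to the zero reference
(negative numbers).  The outer barrier is the highest local maximum in a
declared search window beyond the contact region.  Minima falling within
0.3 σ of the zero-reference separation are not trusted (sparse
extrapolation territory at the edge of the window scan).

## Lipid shells and separation predictions

A single freely diffusing protein is simulated (48 000 steps), every frame
rigidly aligned to the first (least-squares planar rotation of the ring,
reflection fits are an error), and lipid positions accumulated on a square
grid (side 7 σ, 120 bins per side) around the COM, one channel per leaflet.
The density is projected onto lines from the COM (direction 90° — the wide
face's outward normal, i.e. the approach direction of a wide–wide partner;
half-window ±15°, 1° spacing, length 3.5 σ, bilinear interpolation), the
per-leaflet profiles averaged, and shell peaks detected with 3-point
parabolic refinement (prominence 0.05 in per-area density units, minimum
spacing 0.5 σ).  Raw per-cell counts are the stored density; the radial
profiles used for peak detection are normalized per unit area.

The restrained metastable separations are predicted by overlaying the
profile with its x-reversed copy at trial separation s (reversed peak j
lands at s − r_j) and choosing s so the prescribed peak pairs coincide:
n = 1: (1↔1) ⇒ s = 2r₁; n = 2: (1↔2) ⇒ s = r₁ + r₂; n = 3: (1↔3) and
(2↔2), overdetermined, resolved by least squares ⇒ s = (r₁ + r₃ + 2r₂)/2.
The prediction is compared against the quadratic-fitted PMF minima beyond
the contact well.

## Buried surface area

Shrake–Rupley with a deterministic Fibonacci point set (960 points per
sphere by default; 480 in the pipeline profile).  Toy bodies are treated as
spheres of the ring-particle radius (0.3 σ) at their in-plane coordinates
in a single layer, and the probe radius defaults to 0.6 σ — twice the
body-particle radius, a lipid-sized probe, since lipids are the relevant
"solvent" for a membrane interface.  Buried area is
`area_A + area_B − area_complex` on a common probe.  Isolated-body areas
are pose-independent and computed once; frames where no cross-body sphere
pair is within `2(r + p)` have exactly zero buried area by construction and
are short-circuited.  Per configuration, frame-averaged buried areas (10
frames per window) are tabulated against distance from that PMF's minimum
(removing the orientation-dependent contact radius), the area *at* the
minimum is an OLS straight-line fit over ±0.3 σ (flagged if one-sided), and
depth-versus-area across the four orientation presets is summarized by an
OLS slope and Pearson correlation.  Dispersion is reported as the standard
deviation over frames and labelled as such.

## The four orientation presets

(θ_A, θ_B) = (0°, 0°), (0°, 180°), (0°, 90°), (90°, 90°): wide–wide
parallel and anti-parallel, wide–narrow, narrow–narrow.  The toy ellipse is
mirror-symmetric, so the two wide–wide presets are *identical* by
construction up to sampling noise — their independent runs double as an
internal convergence control.  The unrestrained control runs the same
pipeline with k_rot = 0.

## Problem sizes and determinism

The standard experiment (four presets, ≈ 50 windows each, 1 600 samples per
window, one single-protein shell run) is sized for a single CPU: the full
pipeline completes in roughly ten minutes, and all simulations are exactly
reproducible from one master seed (per-window seeds derive from it through
`SeedSequence`; the integrator is single-threaded and bit-deterministic).
Re-running a plan reproduces its output manifest bit for bit.

## What the toy does and does not show

Passing the end-to-end checks demonstrates that the *pipeline* is correct
and self-consistent: WHAM agrees with exact 1D free energies; shell peaks
measured around one body predict the restrained metastable minima of the
two-body landscape within half a lipid diameter; well depth orders with
buried interface area across orientations.  It does not validate any
chemistry: there is no third dimension, no solvent, no lipid internal
structure, no hydrophobic mismatch, and the cohesion well is a one-knob
stand-in for all direct protein–protein affinity.  Quantities carried by
those ingredients (absolute well depths, barrier heights in physical units)
are illustrative only.

## Known limitations

* Deep contact wells make the steep flank between contact and the first
  lipidated state the dominant source of stitching error; the split-half
  discrepancy reported alongside each PMF is the honest error bar, and
  well-depth differences below it should not be interpreted.
* Histogram WHAM has an O(k Δ²) discretization bias if window stiffness and
  bin width are mismatched; the defaults here keep it an order of magnitude
  below sampling noise.
* Peak detection on short single-protein runs can miss the faint third
  shell; predictions for n = 3 are then unavailable rather than wrong.
  Likewise the two-lipid metastable state is only ≈ 1 k_BT deep, and in
  some realizations its prominence falls below the 0.25 k_BT filter at the
  standard sampling scale; the minima table then simply omits it.
* The planar-distance Jacobian tilt is not removed (see above).
* Zero-referencing pins a single bin, so the reference carries that bin's
  sampling noise (a few tenths of k_BT) as a common offset; it cancels
  within a profile but enters comparisons of absolute depths or barrier
  heights *across* independently sampled configurations.  The local shape
  of each feature (locations, curvatures, height above the local plateau)
  is unaffected.
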