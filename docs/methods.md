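# Methods

`chipflow` models a PDMS cell-trapping chip: one input channel (0.96 mm wide
for the 40 µm design, 0.6 mm for the 25 µm design) fans out into 128 parallel
microchannels, 20 mm long and 50 µm deep, each ending in three diamond-shaped
microposts that leave 2 µm of free width per side — culture medium passes,
cells are retained.  The package reproduces the chip's computational
characterization: steady 2D creeping flow, wall-shear statistics, Lagrangian
cell tracing with Stokes drag, and a synthetic displacement-velocimetry loop.

## Flow model

The medium is water-like (ρ = 1000 kg/m³, µ = 0.001 Pa·s).  At the study's
inlet velocities (1.5×10⁻³–6.6×10⁻² m/s) and channel scales, Re = ρUl/µ < 1
everywhere, so the incompressible Navier–Stokes system reduces to the Stokes
(creeping-flow) limit; the solved problem is

    µ ∇²V = ∇P,  ∇·V = 0,

with a uniform inflow of magnitude U_in on the inlet, no-slip walls, and a
zero-pressure (do-nothing) outlet.  The model is plan-view 2D: the 50 µm
depth enters only the conversion U_in = Q/(w_inlet·depth) between syringe
rate and inlet velocity.  No shallow-channel (Hele-Shaw) depth drag is
added; this follows the plain-2D convention of the original characterization
and is the main reason absolute velocities should be read as 2D model
quantities, not mid-depth microscope velocities (a rectangular 40×50 µm duct
runs ≈2× faster at mid-depth than its mean).

Shear stress is reported as the viscous stress magnitude τ = µ·√(2 D:D) with
D = ½(∇V+∇Vᵀ), which reduces to µ|du/dy| in simple shear; 1 Pa = 10 dyne/cm².

## Discretization

No finite-element or mesh-generation library is available in the runtime
environment, so both are implemented in the package:

* **Meshing** (`chipflow.meshing`): boundary rings sampled at a graded
  target size, nested hexagonal interior lattices following the size field
  h(p) = clip(h_fine + 0.35·dist(p, posts), h_fine, h_global), Delaunay
  triangulation (Qhull), outside-triangle removal, and Laplacian smoothing.
  Fully deterministic (no RNG).  Default patch resolution: h = w/8 in the
  channel, h = gap/5 (0.4 µm) at the microposts, i.e. ≥5 elements across
  each 2 µm gap.
* **Stokes solver** (`chipflow.fem`): Taylor–Hood P2/P1 mixed elements,
  degree-4 triangle quadrature, sparse direct solve (SuperLU); recorded
  linear residuals are ~10⁻¹²–10⁻¹⁴.  Plane Poiseuille flow is quadratic,
  so the element reproduces it to solver precision — the Poiseuille profile
  and the 6µU/w wall-shear closed form are the primary verification oracles.

## Composite full-chip model

A monolithic mesh of the full chip (128 × 20 mm channels with 0.4 µm gap
resolution) would need ~10⁷ elements.  Instead the chip is decomposed,
exploiting linearity of Stokes flow and the fully developed state of the
long channels:

* inlet/outlet feed channels: closed-form plane Poiseuille at the imposed
  flux;
* tapered headers: one FEM patch at unit inlet velocity (uniform inflow,
  open outflow);
* straight channel runs: closed form at the per-channel flux from the
  hydraulic-resistance network (R = 12µL/w³ per unit depth; for 128
  identical channels the partition is exactly 1/128 — the header's series
  resistance is ~10⁹ times smaller than a channel's);
* micropost row + 200 µm collection segment: one FEM patch at unit
  channel-mean velocity with parabolic inflow, reused for every channel.

Surface statistics are area-weighted combinations of region integrals; all
scale exactly linearly in U_in, so a 6-velocity sweep costs one pair of
patch solves.  On an 8-channel miniature chip solved monolithically, the
composite averages agree within 3% and FEM per-channel fluxes match the
network within 2%; a full-chip monolithic cross-check is not feasible, so
these miniatures carry that verification.  The miniatures omit microposts:
the post region is handled by the identical FEM patch in both paths, so the
comparison deliberately stresses the manifold stitching, which is where the
approximation lives.

### Geometry defaults where the publication prints none

Channel pitch = width + 25 µm wall; tapered trapezoidal header of length
2 mm widening to the array height (a `straight_header` alternative exists
for tests); feed channels of the printed width and 5 mm length at each end
(the published velocity profile along the input-channel centreline shows a
developed plateau, so a feed several widths long exists); diamond posts
with transverse diagonal = width − 2·gap and equal axial diagonal,
tip-to-tip clearance of one axial diagonal, last post 50 µm from the
channel end.  All are configurable; all were fixed before any comparison
runs and not revisited.

## Known discrepancies with the published tables

* **Surface-average shear** (the quantity both headline numbers use) lands
  at −3.6% (40 µm, 1.451 vs 1.504 dyne/cm²) and −10% (25 µm) — inside the
  15% geometry-uncertainty band.  The 250 µl/day dynamic-culture value
  follows by exact linear scaling (7.12×10⁻³ vs 7.34×10⁻³ dyne/cm²).
* **Surface-average velocity** comes out ~20% below the published rows.
  The published chip-average velocity (0.0039 m/s at U_in = 0.0123 m/s)
  can only be produced by fast manifold regions covering ~15% of the chip
  area at ≈1.2·U_in — several millimetres of wide input channel that the
  publication does not dimension.  With the defaults above the model's
  manifold is smaller; the deficit is a geometry-area effect, not a solver
  error (average shear, which weights the same regions near zero, is
  unaffected).  The geometry was not enlarged to chase these rows.
* **Surface-maximum shear** exceeds the published 926/927 dyne/cm² by
  23–33%.  The sharp diamond tips are re-entrant corners at which Stokes
  stress is singular (τ ~ r^(λ−1), λ ≈ 0.54), so any reported maximum is a
  mesh regularization of an unbounded quantity; at gap/5 resolution the
  corner is resolved more finely than in the original (unstated) mesh.
  Surface-maximum velocity is bounded and resolution-stable and matches
  within 6%.
* **Mesh convergence**: chip-level average shear changes by <0.3% per patch
  refinement level (the patch contributes ~12% of the chip integral and its
  own average moves <2% per level, dominated by the slowly-converging
  corner integral).

## Cell transport

Cells are passive spheres with Stokes drag F = 3πd_pµ(V−V_p) and no lift or
Magnus force.  Their relaxation time ρ_p·d_p²/(18µ) ≈ 8.4 µs (12 µm,
1050 kg/m³) against second-scale transits, so the default **tracer** mode
integrates dx/dt = V(x) with RK4.  The **inertial** mode integrates the
first-order Stokes-number (slow-manifold) correction
dx/dt = V − τ_p(V·∇)V and records the implied drag force; a stiff
velocity-ODE integrator was rejected because step noise, not physics,
dominated it.  Tracer and inertial trajectories agree within 0.1% of the
channel length for ≥95% of cells; rare cells convert a genuine inertial
arrival-time lag at a channel mouth into a position offset amplified by the
header→channel speed ratio (≤0.5%).

Diameters are truncated-normal (±3σ) with cv defaults 0.10/0.15/0.17/0.22
for 8/12/14/19 µm means (wider for larger cells, matching the qualitative
observation); cv ≥ 1/3 is rejected.  Release is uniform in y at the inlet
face with fluid-coupled initial velocity.  Each cell carries its streamline
label — the cumulative flux fraction at the uniform inflow face — and the
header→array junction assigns channel and transverse position from that
label.  Recomputing the label from the integrated position was tried first
and rejected: it amplifies O(10⁻⁴) integration noise 128-fold and breaks
the exact linearity of trajectories in U_in.

Trapping: a cell with diameter > 2·side-gap is trapped when its centre
crosses a line one radius upstream of the first micropost tip; smaller
particles pass through the gaps (integrated through the micropost FEM patch
with substeps capped at a quarter gap per step).  An optional queueing mode
stacks arrivals one diameter behind the cell in front (off by default — the
published tracing shows no cell–cell interaction).  One-way coupling only:
trapped cells do not perturb the flow; channel-blocking feedback is a known
limitation.

**Release schedule.** A batch release (all cells at t = 0) is the default
and matches the published description of the tracing setup, but it puts the
in-channel position histogram's mass at the advancing front: flux-weighted
streamline sampling concentrates cells near the flat peak of the parabola,
so counts *rise* toward the outlet.  The published histograms fall toward
the outlet, which is the signature of continuous injection (cells entering
steadily, slow ones accumulating near the entrance).  The histogram
statistics therefore use the continuous-release mode (uniform release times
over an 8 s window); trapping, occupancy and speed measurements use the
batch default.

**Traced cell speed.**  The validation measurement averages frame-pair
displacements |Δx|/Δt at 30 fps for cells inside the microchannels, over
the window from release to first terminal-micropost arrival (the snapshot
convention of the trajectory figures).  Mass conservation pins this number:
Q = 2.12 ml/h splits equally over 128 channels of 40 µm, giving a mean
channel velocity of 2.30×10⁻³ m/s, a centreline maximum of 3.46×10⁻³ m/s
and a flux-weighted tracer mean of ≈2.8×10⁻³ m/s.  The published
"numerical" cell speed of 3.98×10⁻³ m/s exceeds the centreline maximum and
equals the published chip-wide surface-average velocity (0.0039 m/s) to
1.3%; no mass-conserving in-channel tracer measurement can reproduce it in
this model.  The package reports its own 2.76×10⁻³ m/s honestly.  (The
*experimental* 3.71×10⁻³ m/s is consistent with mid-depth imaging of the
real 3D duct, where the mid-plane runs ~1.6–2× faster than the 2D mean.)

## Synthetic velocimetry

Trajectories are rendered to 30 fps centroid lists in pixel coordinates
with Gaussian centroid jitter; the ground-truth pixel size is withheld from
the estimator, which must recover scale from integer-pixel wall marks of
one channel (the known 40 µm width).  Linking is greedy nearest-neighbour
with constant-velocity prediction once a track has two points; the gating
radius is 1.5× the per-frame displacement expected from the flow solution
(the data-driven fallback underestimates the gate in dense arrival fronts).
Per-track mean speeds are averaged over tracks of ≥10 positions.  The
round trip (render → estimate) recovers the track-weighted traced mean
within 5% at jitter ≤1 px in a microscope-realistic scene (mid-channel
field of view, ~1 cell per 5 channels); at full scene density (1000
simultaneous cells, displacement per frame > channel pitch) linking
fragments and the estimate biases ~7% low — a real limitation of NN
linking at 30 fps, noted rather than hidden.

## What the synthetic data do and do not show

The generator emulates: size-distributed cell populations, seeded random
release, steady creeping flow, frame-rate imaging with centroid noise and
pixel quantization.  It does not emulate: 3D depth profiles, cell
deformation or adhesion, cell–cell hydrodynamic interaction, syringe
sedimentation, fabrication defects (missing posts), illumination or
segmentation errors in real video.  Passing tests therefore validate the
numerical machinery and the model's internal consistency, not the full
fidelity of the physical device.

## Problem sizes

Defaults chosen for single-CPU runs: micropost patch ~2.7×10⁴ triangles,
header patch ~3×10³, miniature verification chips 1–4×10⁴; tracing studies
release 10²–10³ cells (statistics scale per-cell, independent of the
physical 1.4–2×10⁶ per 170 µl; the histogram/occupancy tests state their
scaled counts).  One full composite model builds in ~10 s; the five-seed
traced-speed measurement takes ~1 min.
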