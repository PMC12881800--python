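# Methods

## Scope and data flow

The package models the interactive part of an image-guided lung
resection workflow. Its input is a labeled 3-D volume (integer codes:
background 0, five lobes 1–5, pulmonary artery 6, vein 7, bronchial
tree 8, tumor 9) with a voxel-to-world affine in millimetres; the
label convention is fixed by the package because segmentation tools do
not share one. Four stages follow: synthetic phantom generation (so no
patient data is required), FEM meshing, deformable simulation, and
concordance evaluation against surgeon-adjudicated structure counts.

## Synthetic thorax phantom

The phantom emulates the *geometry* of a thoracic CT segmentation, not
its intensities. Each lung is an ellipsoid (radii ≈ 0.17/0.27/0.36 of
the grid extent) with a low-order sinusoidal boundary ripple so the
shape is not a perfect quadric; seeded jitter moves centers and
fissure-plane normals between seeds. Fissure planes cut the left lung
into 2 and the right into 3 lobes; a band of one voxel half-width on
each side of every plane is cleared, which guarantees the lobes are
pairwise disjoint with at least one empty voxel between them. The
pulmonary artery, vein and bronchial tree are recursive bifurcating
cylinder trees: a depth-d tree has 2^d terminal tips, child radius and
length shrink geometrically (defaults 0.75 each), sibling branches
leave the parent at ≈35° with seeded jitter, and the first bifurcation
is steered laterally so one child enters each lung. Cylinders are
rasterized by a distance-to-segment test; paint order is lobes, tumor,
artery, vein, bronchus (later wins). Generation is bit-reproducible
from the config: all randomness flows through one seeded generator,
and radii never consume random draws, so two configs differing only in
`radius_decay` share identical centerlines (the basis of the
monotonicity property test).

Configurations that cannot be honored fail loudly instead of
truncating: a tree whose reach exceeds ~half the grid, or whose
terminal radius falls below 0.45 voxels (unrasterizable), raises.

What the phantom does **not** emulate: CT noise and partial-volume
effects, segmentation errors, true lobar/vascular topology (each tree
is a symmetric binary tree), lung desufflation, and tissue
heterogeneity within a label. Tests passing on the phantom therefore
validate the pipeline's mechanics and bookkeeping, not anatomical
fidelity on clinical data.

## Surface extraction

Structure surfaces are marching-cubes isosurfaces taken on the zero
level set of the mask's signed distance field, smoothed by a 0.5-voxel
Gaussian. Binary-mask isosurfaces carry a staircase artifact that
inflates area by ~9%; the smoothed distance field reduces the sphere
area error to under 4% while a 0.5-voxel kernel is small enough that
one-voxel-thin branches survive (a fallback re-extracts without
smoothing if a structure would vanish entirely). Masks are padded so
surfaces always close; orientation is normalized to outward normals
(positive enclosed volume). Phantom surfaces are watertight, which the
suite verifies with trimesh as an independent oracle.

## FEM meshing

A deliberate lattice mesher rather than Delaunay/advancing-front: the
masked region's bounding box is tiled by a regular grid of cells, each
cell split into five tetrahedra with the split mirrored in a
checkerboard pattern so faces shared between cells conform. A
tetrahedron is kept when its centroid's voxel lies in the mask; its
tissue label is that voxel's code. The lattice pitch is bisected (42
iterations, with all evaluated pitches remembered) to make the kept
count the closest achievable to the requested element budget, ties
resolving to the coarser pitch. Because cells stretch to tile the
bounding box exactly, a full-box mask meshed at budget 5 reproduces
the box volume to rounding error. Centroid keeping is approximately
unbiased at boundaries (gains from protruding kept elements offset
losses from dropped ones); phantom lobes at the default budget land
within a few percent of the voxel volume, and the suite enforces 15%.

The default budget is 4096 tetrahedra per patient model — the whole-
model element count this class of interactive simulation targets —
shared across the five lobes proportionally to lobe voxel volume by
largest-remainder rounding. Each lobe is one FEM mesh; vessels and
airways are not meshed separately. Instead, vessel/airway/tumor voxels
within 2 voxels of a lobe are absorbed into its mask, so elements
crossing them pick up the stiffer tissue label. Meshes serialize to a
plain JSON layout (nodes, tets, tissue, element_budget).

## Barycentric embedding

Each surface vertex is assigned to one cage tetrahedron with
barycentric weights (sum exactly 1). Candidates come from a k-d tree
over element centroids (k = 32); among containing elements the lowest
element index wins, making assignment deterministic when a vertex sits
on a shared face. Vertices outside every candidate — marching-cubes
surfaces protrude beyond a centroid-kept cage — fall back to the
nearest candidate centroid with weights clamped to [0, 1] and
renormalized; the clamped fraction is reported on the map rather than
hidden. For interior vertices the rest-pose round-trip is exact to
floating point (< 1e-6 mm asserted).

## Materials

Isotropic linear elasticity per tissue: Young's modulus E (kPa),
Poisson ratio ν in [0, 0.5) (ν = 0 admitted for analysis), density ρ
(kg/m³), Rayleigh damping α (1/s, mass-proportional) and β (s,
stiffness-proportional). Defaults:

| tissue      | E (kPa) | ν    | ρ (kg/m³) |
|-------------|---------|------|-----------|
| parenchyma  | 5       | 0.35 | 400       |
| vein        | 60      | 0.45 | 1100      |
| artery      | 100     | 0.45 | 1100      |
| bronchus    | 200     | 0.40 | 1100      |
| tumor       | 30      | 0.40 | 1050      |

These are engineering choices in the ranges soft-tissue simulation
commonly uses, ordered parenchyma < vein < artery < bronchus; every
field is overridable per tissue and overrides propagate into assembly.
Damping defaults α = 8 /s, β = 5e-4 s were chosen from the integrator
analysis below: together they settle a released lobe in a fraction of
a second to a few seconds of simulated time while guaranteeing
per-step energy dissipation at the automatic substep size.

Internal units are mm–g–s (1 kPa = 10³ g·mm⁻¹·s⁻², 1 kg/m³ = 10⁻⁶
g/mm³, forces in µN); all public interfaces stay in mm and seconds.

## Dynamics

Element stiffness K_e = V Bᵀ D B from linear tetrahedral shape
functions; lumped mass ρV/4 per node. Forces are corotational: R_e
from the polar decomposition (SVD with sign correction) of the
deformation gradient F = D_s D_m⁻¹, f_e = −R_e K_e (R_eᵀ x_e − X_e).
This is exact at rest and under rigid motion, matches the linear model
to first order at small strain (≤1% at 0.1%-of-diameter
displacements, asserted), and conserves linear momentum identically
because the stiffness annihilates translations. Inverted elements
(det F < 0) keep the sign-corrected rotation and are counted in the
force metadata, not fatal. Displacements below 1e-9 mm per element are
treated as exact zeros — far below any physical motion — so the rest
pose is an exact equilibrium despite SVD rounding.

Integration is semi-implicit Euler: v' = (v + Δt(f_el + f_ext −
β R K Rᵀ v)/m)/(1 + αΔt), x' = x + Δt v'. The mass-damping term is
implicit (diagonal, unconditionally stable); the stiffness-damping
term is explicit. Explicit stepping of kilopascal tissue on
centimetre elements is far stiffer than the 1/90 s frame budget
allows, so `run_simulation` keeps the user-facing frame grid but
subdivides each frame into substeps sized from a 30-iteration power-
iteration estimate of the highest elastic frequency ω: Δt_sub =
0.25 · min(2/ω, 2/(βω²)). A per-mode analysis of the damped update
shows energy decays monotonically when βω ≳ 0.25, which the β default
satisfies for the element sizes the mesher produces; the suite asserts
non-increasing mechanical energy (kinetic + corotational elastic) at
every step. Non-finite positions raise an error advising a smaller dt
or more damping. The dynamics contain no randomness: identical inputs
give bit-identical traces.

## Scripted deformations, boundary conditions, instrumentation

The five default inputs emulate pulling lobes apart along their
fissures: for each lobe the handle is the decile of surface vertices
nearest (by projection) to the adjacent lobe of the same lung, the
displacement points away from that lobe with magnitude 10% of the
lobe's bounding-box diagonal (amplitude proportional to lobe size),
and the input always lasts 0.1 s. Handles ramp linearly and release
with their ramp velocity. Because an unconstrained lobe would drift,
the 5% of mesh nodes nearest the mediastinal point (the hilum side)
are pinned by default.

Traces record, per 1/90 s frame, the simulated time, the mean node
displacement relative to the previous frame (mm), and the wall-clock
duration of the frame's computation. Convergence time is the
simulated time from input end until mean frame displacement stays
below ε = 1e-3 mm for 10 consecutive frames (+∞ if never). Frame-rate
statistics (1/wall-duration per advanced frame) are explicitly
hardware-dependent diagnostics, not model outputs: the suite checks
their bookkeeping and the qualitative behaviors (settling well within
5 s of simulated time after the 0.1 s pull; convergence time finite
and decreasing as damping rises from 0.1× to 1× of default), not
wall-clock numbers.

## Concordance evaluation

Counts-only TP/FP/FN (TP = min, FP/FN = the excess on either side) is
the default because the shipped 30-case table records only counts and
this rule recovers each of its narrated discrepancies (an extra model
artery in case 15, a missing artery in case 23, extra veins in cases
11 and 18). It cannot detect offsetting identity errors — one missed
plus one hallucinated branch of the same type cancel — so explicit
TP/FP/FN may be supplied through `ConcordanceCounts` directly. TN is
identically zero, which implies accuracy ≤ min(precision, sensitivity)
for every defined case (asserted over the fixture and random counts).
Aggregation macro-averages per-case scores over evaluable cases;
undefined scores (zero denominators) and missing counts are excluded,
never imputed, and the evaluable n is always reported so transcription
differences in the fixture's `x` cells stay visible. The spread is
the sample (n−1) standard deviation, which matches the reported
per-structure spreads; a population-sd option exists. Two fixture
cells (case 11's vein pair) are the hardest to read in the source
table; the transcription used here is (video 1, model 2) and is
validated by the aggregate means it produces.

## Problem sizes in the test suite

Suite runs use a 64³ × 2 mm phantom (seed 7), a ~300-element
parenchyma-only lobe cage for the 5 s settling run, a ~40-element
cage for the damping comparison (12 s horizon), a 60-element
clamped bar for the static stiffness-doubling check, and six phantom
seeds for the orientation sweep. These sizes are the package's chosen
desk-scale defaults; all behaviors they exercise are size-independent
contracts (conservation, invariance, monotonicity), not tuned
quantities.

## Known limitations

- Counts-based concordance is blind to offsetting identity errors and
  to branch-origin mistakes that leave counts unchanged.
- The lattice mesher offers no adaptive refinement, smoothing or
  hexahedra; very thin masks mesh coarsely or not at all.
- No collision or contact between lobes; pulled lobes can
  interpenetrate neighbors.
- No desufflation model: meshes rest in the inflated (preoperative)
  configuration.
- Explicit substepping makes very stiff, near-incompressible tissues
  (ν → 0.5) expensive; an implicit solver is out of scope.
- Frame-rate numbers measure this machine and this Python
  implementation, nothing more.
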