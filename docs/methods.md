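# Methods

`emassemble` assembles several rigid, coarse-grained protein components
simultaneously into a low-resolution cryo-EM density map.  This note
documents the model, its parameters and defaults, the numerical choices,
what the synthetic benchmark does and does not probe, and the known
limitations.

## Density model

Every bead (pseudo-atom) and every map voxel is an isotropic 3D Gaussian.
All Gaussians tied to a map of nominal resolution *R* share the per-axis
standard deviation

    sigma = (R / 2) / sqrt(3),

so the width of the full 3D Gaussian matches half the resolution; the
divisor is exposed as a parameter (`sigma_from_resolution(..., divisor=)`).
Simulated maps deposit one Gaussian per bead, normalised so each bead's
integral equals its weight (summed atomic masses): `sum(values) * voxel^3`
approximates the total weight.  Values live at voxel centers; the world
coordinate of voxel (i,j,k) is `origin + voxel_size * (i,j,k)`.  The
resolution-to-voxel ratio defaults to 4 and deviating from it triggers a
warning, because gradient-vector matching degrades away from that ratio.
Experimental maps with finer voxels are adapted by joining neighbouring
voxels (summation, so the density sum is conserved exactly) and, where
needed, Gaussian low-pass filtering to the target resolution; maps are then
rescaled to the simulated-map density sum before use.

## Gaussian-overlap fitting energy

The overlap of two Gaussians with amplitudes A1, A2 and decay factors
s = 1/(2 sigma^2) is itself a Gaussian of the center distance D:

    O(D) = A1 A2 (pi / (s1 + s2))^{3/2} exp(-(s1 s2 / (s1 + s2)) D^2),

validated against numerical integration in the test suite.  Summing a
probe atom's overlap over *all* voxels of the map cannot be truncated (far
voxels contribute), so it is precomputed per voxel as an exact discrete
convolution (FFT, full-extent kernel).  Alongside O, the analytic gradient
and the analytic mixed partials (Oxy, Oxz, Oyz, Oxyz) are precomputed the
same way; at run time the overlap at an arbitrary position is a tricubic
Hermite interpolation from the eight surrounding voxels.  The plain
trilinear variant is available (`method="trilinear"`), but on ratio-4 grids
its relative error against the direct summation is at the percent level,
whereas the Hermite form stays below 1e-3 in the fitting region; the
trilinear *weights* (which sum to 1) are still what fractionally deposits
each bead onto its eight neighbouring voxels for the atom-density grid.

Each bead's *maximum overlap* m is calibrated by simulating the component's
own map at the working resolution and recording the bead's interpolated
overlap at its own position (intramolecular spillover is thereby included).
Deficiencies are measured relative to m, so all amplitude conventions
cancel:

    d_hard = max(0, 1 - O/m),     d_soft = max(0, 1 - O/(F m)),
    E = sum_beads k_hard d_hard^2 + k_soft d_soft^2,

with k_hard : k_soft = 100 : 1 by default (a large penalty below the
bead's own maximum, a much smaller one below F times it).  F >= 1 models
intermolecular spillover from adjacent subunits; it is a per-system,
per-resolution calibration constant (reference systems in the literature
used 5.1 at 40 A and 1.7 at 20 A for a seven-membered ring; the synthetic
benchmark calibrates its own F from the reference structure as the 5th
percentile of the observed overlap-to-maximum ratio, which lands at a
comparable 4.3 / 1.4 for the default three-ring toy).  Forces are the exact
analytic gradient of the implemented (interpolated) energy, so they agree
with central finite differences to better than 1e-4; out-of-grid beads are
clamped to the boundary cell, whose slope supplies the inward pull.

This fitting term is deliberately *local and permissive*: any placement
inside dense regions satisfies it.  Specificity comes from the clash term,
the symmetry restraints and GVM re-ranking, not from the overlap term.

## Voxel atom density and the clash term

The trilinear deposit of bead weights yields the "voxel atom density"
grid.  A quadratic penalty `k_clash * sum max(0, density - cap)^2` with the
exact gradient through the deposits keeps components from interpenetrating.
Caps are quoted in average-pseudo-atom counts per voxel (published values:
18 for 40 A maps, 16 during refinement, 4 for 20 A maps) and converted to
the mass units beads carry by multiplying with the assembly's mean bead
weight.  The synthetic benchmark calibrates its caps from the reference
structure's own voxel densities (+25% headroom in assembly, +10% in
refinement), mirroring how the published caps were measured on their
reference complex.

## Gradient vector matching (GVM)

Contours are read as planes whose normals are the local density gradient,
computed with the unnormalised 3D Prewitt operator (a linear ramp of unit
slope gives |V| = 18).  V_exp comes from the fine map, V_model from the
model's voxel atom-density grid, scaled by a constant correcting their
systematic magnitude ratio (1.35 in the reference study; recalibrated per
system by the provided least-squares helper — the toy benchmark lands
around 0.33-0.37 because its atom-density grids are spikier relative to
its maps).  Before comparison the map is rescaled so its density sum equals
the model's total bead weight, making the two fields commensurate.  Voxels
with |V_exp| >= 2 (Euclidean norm; a per-component mode is available)
contribute, per Cartesian component, `penalty * max(0, |dV| - tolerance)^2`
with tolerance 2 (20 for large multi-ring systems).  GVM is a ranking
score only; it is never differentiated into a force.

## Symmetry, location and gravity restraints

C_X symmetry is enforced with distance-equality restraints and no explicit
symmetry axis: backbone beads pair as (C_i, C_{p-i}); each pair contributes
equality sets S_k (k = 1 .. floor(X/2), so C7 yields S1-S3 and C2 still
gets one set) holding the X cyclically shifted distances d(A_n, B_{n+k})
with monomer indices modulo X.  Within a set, each distance is restrained
to the set mean: deviation D, force -c D along the pair axis, energy
0.5 c D^2 per entry, c = 0.005 kcal/mol/A.  The energy is the exact
integral of the force, so rankings, minima and finite-difference checks
are all consistent.  D4 restraints implement the three two-member
equalities of the dihedral tetramer.

Location restraints pin a component's weighted center of mass to a target
with E = 0.5 k |d|^2, k = 0.5 kcal/mol/A by default; the restoring force is
distributed over beads in proportion to weight (the exact COM chain rule).
Uniform (-5, 5) A per-axis offsets produce the expected mean displacement
of 4.8 A.  "Gravity" is a pre-assembly device: weak harmonic attraction
(0.001) between all COM pairs plus strong harmonic repulsion (1.0) inside
0.8x the summed radii of gyration; radii of gyration are pose-invariant
model constants so the gradient is exact.

## Stand-in intermolecular potential

Refinement needs short-range packing forces between subunits.  A soft 8-6
pair potential `depth * (3 (rmin/r)^8 - 4 (rmin/r)^6)` acts between beads
of different components, smoothly switched off between 12 and 15 A, with a
single generic bead type by default and per-kind tables loadable from a
text format.  It is a generic packing potential: the staged protocol needs
its presence (interface tightening), not any particular parameterisation.
The toy benchmark sets rmin to the subunit's median internal bead-packing
distance with a shallow 0.02 kcal/mol well, so the reference structure is
near force balance rather than blown apart.

## Rigid-body minimization

Six degrees of freedom per unfrozen component: translation plus an
incremental axis-angle rotation about the component's weighted COM,
re-anchored after every accepted step so that the packed gradient (net
force; torque divided by the component's radius of gyration, which balances
the translational and rotational step scales) is exact at each expansion
point.  Descent uses a Barzilai-Borwein trial step with Armijo
backtracking: accepted energies are monotone non-increasing by
construction.  Rotations are re-orthonormalised each step (one Newton
iteration of the polar decomposition; drift stays below 1e-9).
Convergence: |dE| below `tol` (default 1e-9 — energies are dimensionless
after deficiency normalisation) or `max_iter`.  A NaN from any term aborts
with a diagnostic naming the term.  Orientation-only minimization freezes
translations; per-component freezing is available through the stack mask.

## Staged protocol

1. **Starts** — uniform random poses in a box, or ring-topology priors:
   per ring, a shared axial jitter U(-5, 5) A, radius U(mean +/- halfwidth),
   random phase, the remaining subunits evenly spaced, orientations uniform
   over SO(3).  One master seed; each structure's stream derives from
   (seed, index), making pools order-independent and reproducible.
2. **Pre-assembly** — symmetry energy minimized (orientation-only when the
   positions are already symmetric), map and atomic terms off; pool sorted
   by symmetry energy and truncated.
3. **Assembly** — EM fit + clash + symmetry (+ gravity) against the coarse
   (40 A-class) map; sorted by total energy.
4. **Scoring** — truncate by assembly energy, re-rank by GVM against the
   fine map.
5. **Refinement** — four sub-stages: (a) the fine map's term joins the
   coarse one; (b) intermolecular forces at weight 0.01; (c) full forces
   with the map terms upweighted by 50 (prevents disintegration); (d) all
   weights 1.  Final re-rank by GVM.

Recombination swaps component blocks (rings) between every ordered pair of
top parents (P parents, m patterns -> P(P-1)m children before removing
bit-identical duplicates; 100 parents with 2 patterns give the canonical
19 800).  Its placement is configurable: after scoring (the classical
arrangement) or after refinement, which the synthetic benchmark uses with
two rounds — see below.  An optional final polish re-minimises the leaders
with the full stack and re-ranks by GVM.

Stage weights are explicit configuration.  The published protocol balances
the symmetry constant against force-field-unit map energies; with the
dimensionless deficiency energy used here, the equivalent balance is set
through the symmetry stage weight.  The synthetic benchmark runs with a
stiff symmetry weight (3e5) in the assembly stage and in refinement
sub-stage (a), which makes each ring rotate quasi-rigidly, turning the
orientation search into 3 collective degrees of freedom per ring — the
mechanism by which a desk-scale pool can lock subunit orientations at all
(see below); the later sub-stages release the coupling (weight 1) so that
individual subunits settle into their seats.

Pool sizes: the reference schedule is 10^6 starts -> 5x10^5 -> 10^5 scored
-> 10^3 refined; the desk preset is 2000 -> 1000 -> 200 -> 20.  A
largest-relative-gap selector (with fixed-count fallback) generalises
picking a clearly separated leading cluster for refinement.

## The synthetic benchmark: what it emulates, and what not

`synthetic` builds ring stacks of rigid bead blobs with exact per-ring C_X
symmetry (identical copies within each ring), simulated maps at a
coarse/fine resolution pair (voxel = resolution/4), labelled decoy pools,
and a wired protocol configuration.  The default is three stacked 7-fold
rings (21 subunits, 32 beads each, bead weight ~110): a small cap ring
(subunits scaled by 0.72, radius 38 A, z = -30 A) over two body rings
(radius 44 A, z = 0/+30 A).  The subunit is a three-lobe blob with graded
lobe masses on a scalene triangle and the light lobe lifted out of plane,
so no flip or mirror reproduces its low-resolution envelope — orientation
is identifiable from density alone, which the tests rely on.  The distinct
cap makes ring blocks structurally distinguishable (a ring-swapped
negative control is meaningful), and the rings are sparse: neighbour gaps
exceed the fine-map kernel width.

Per-system constants are calibrated from the reference structure exactly as
one would for a new real system: spillover F per resolution, clash caps
from reference voxel densities, and the GVM model-gradient scale.

Known divergence from protein reality, and its consequence: convex
Gaussian blobs have no interlocking interfaces, and at a 40 A-class
resolution a closed ring of them smears into a near-uniform torus, so the
coarse map carries almost no orientation signal for in-ring subunits.  The
assembly stage therefore fixes positions, ring phase and radii but not
subunit orientations (matching the published observation that assembly-
stage top structures sit tens of Angstroms from the truth).  Orientations
lock in refinement sub-stage (a): with the stiff symmetry weight each ring
performs a 3-DOF seating search against the fine map.  Ring sparseness is
what makes that search effective — in tightly packed rings a subunit's
lobes are attracted into neighbouring density bumps and translation can
compensate rotated seatings at near-degenerate energy, collapsing the
native basin; with sparse rings the in-ring orientation landscape
approaches the isolated-subunit one.  The pool supplies repeated draws,
two rounds of ring recombination after refinement combine the best rings
from different parents, GVM selects them, and the final polish settles the
seams.

A hard limitation, measured carefully on this benchmark: the seating
search has a small native basin (only draws within roughly 10-15 degrees
of the true seating converge below 2 A; a competing, locally stable
attractor family sits 3-5 A (about 20 degrees) away, and flip families
further out), and GVM — like the overlap energy — separates truly correct
seatings from everything else but cannot order structures *within* the
flawed families.  Full sub-2 A recovery of all three rings at desk-scale
pool sizes is therefore a stochastic outcome (observed at some seeds, not
others); reliably reaching it needs orders-of-magnitude larger start pools,
exactly as the reference-scale schedule provides.  What the desk-scale run
recovers reliably is the assembly's architecture: ring radii, axial
positions, phases and near-native (few-Angstrom) ring seatings.  Passing
tests demonstrate the pipeline's search-rank-refine logic under exact
rigid-body arithmetic and noise-free maps; they do not demonstrate
robustness to conformational flexibility, map noise, or masking, none of
which the generator models (optional voxel-wise Gaussian noise only).

## Numerical choices and degenerate inputs

- Superposition: closed-form Kabsch via SVD, reflections resolved to
  det = +1; < 3 points or collinear sets raise.
- Trilinear/tricubic cells: positions outside the grid are clamped into
  the boundary cell and flagged; deposits outside the grid are dropped and
  counted.
- Wiener deconvolution divides by the Gaussian transfer function with a
  Tikhonov floor (1e-8 by default), so a zero-width PSF is the identity to
  1e-6; Richardson-Lucy operates on the non-negative part.
- Zero-distance bead pairs in restraints get a zero direction vector
  (measure-zero configuration; the energy is still correct).
- Duplicate removal in recombination is bit-identical pose comparison —
  no clustering.
- Symmetry-energy logging uses the single consistent form 0.5 c D^2; a
  printed variant linear in D that circulates in the literature is treated
  as an erratum (it is not the integral of the stated force).

## Limitations

- Rigid bodies only: no internal flexibility, no normal modes, no
  multi-conformer copies.
- Isotropic voxels only; no CTF model, no FSC estimation, no map
  symmetrization.
- GVM is scoring-only; its gradients are not integrated into minimization.
- The intermolecular potential is a generic stand-in; quantitative
  interface energetics are out of scope.
- Desk-scale pools trade sampling depth for runtime; the reference-scale
  schedule (10^6 starts) is expressible through `StagePlan.paper_scale()`
  but takes CPU-days.
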