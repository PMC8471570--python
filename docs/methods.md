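# Methods

`scaffoldnet` implements an image-based workflow for predicting the
mechanical behaviour of tissue-engineering scaffold unit cells: a
library of porous 5 × 5 × 5 mm³ lattices is generated procedurally,
converted to "digital tomographies" (stacks of binary cross-section
images, the way a lithographic 3D-printing slicer cuts a CAD model),
labelled with porosity and relative elastic moduli by a voxel
finite-element homogenizer, expanded by volumetric data augmentation,
and used to train a small 3D convolutional network that regresses the
three properties from geometry alone.

This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Scaffold library

Hand-designed CAD collections of scaffold unit cells are typically
assembled by solid modelling and boolean operations. The package
replaces manual CAD with four parametric families defined by analytic
solid/void indicator fields:

* **strut grids** — unions of axis-aligned square-section struts of
  width *w* on a period-*p* grid. The solid fraction has the closed
  form 3a² − 2a³ with a = (L/p)·w/L, which the tests use as an oracle.
* **trusses** — cylindrical struts of radius *r* between seeded random
  nodes; the four vertical cube edges are always included so a
  compressive load path exists.
* **implicit-surface cells** — the solid network g(x) ≤ level of the
  gyroid field g = sin x̃ cos ỹ + sin ỹ cos z̃ + sin z̃ cos x̃, with x̃
  scaled to an integer number of periods per cell. Level 0 splits the
  cell 50/50; the representable range is |level| < 1.5.
* **inverse cells** — voxelwise complements of another member,
  emulating subtraction of a scaffold from the bulk cube. Complements
  act on the indicator field / voxel grid, never on meshes: robust
  mesh CSG is not needed because every consumer downstream is
  voxel-based.

Meshes are produced by marching cubes over the indicator sampled on a
100³ grid (0.05 mm per sample, matching the mesh precision commonly
used when exporting scaffold CAD models to STL). Sampling is padded
with a void ring so the surface closes; the result is watertight by
construction, which the parity slicer requires.

The default library holds 20 training and 8 disjoint test specs chosen
once to span voxelized porosities from ≈6 % to ≈94 %, including
complementary pairs (porosity p and 100 − p), mirroring the spread a
diverse hand-designed collection exhibits. The specs are frozen in
`geometry.default_library`; porosity coverage of at least [10 %, 90 %]
is asserted by the tests.

## Virtual tomography

A cell is cut into `n_slices = 20` binary images at
`spacing = 0.25 mm`; slice k lies at the **layer midpoint**
z_k = (k + 0.5)·spacing, so every plane is strictly inside the cell
and coplanar facet/plane intersections cannot occur (commercial
slicers do not document their plane placement; midpoints are the
choice that makes parity rasterization unambiguous). Default lateral
resolution is 1440 × 1440, each pixel 5 mm/1440 on a side.

Rasterization rule: a pixel is material iff its center is interior to
the cross-section under even-odd parity along a +x ray; boundaries
follow a half-open [low, high) convention, so the rule is exactly
reproducible by a brute-force point-in-solid oracle (tested on random
axis-aligned box unions, where parity equals the count of covering
boxes mod 2). Image row 0 is minimum y, column 0 minimum x, and
`occupancy[x, y, k] = slice_k[row(y), col(x)]` everywhere in the
package.

For the CNN, slices are resized to 32 × 32 — a 45 × 45 block mean
followed by re-binarization at 0.5 (ties → material). The block mean
preserves material fraction best among simple resamplers, and
re-binarization is required because the network consumes arrays of 0s
and 1s; 1440² → 32² reduces the pixel count by a factor of 2025.
The experiment pipeline rasterizes at 160 px directly (an exact 5×
oversampling of the 32-px target) rather than 1440 px: the block mean
is identical in structure and the saved rasterization time is spent on
training instead. Full-resolution slicing remains available and is
exercised by the tests.

## Labels: voxel homogenization

Porosity is the void-voxel percentage of the working volume. The
moduli labels are computed by linear elasticity on the occupancy grid:

* material voxels become trilinear 8-node hexahedral elements
  (anisotropic box elements: 5/n mm lateral, cell-height/n_z axial,
  2×2×2 Gauss quadrature);
* the bottom face (z = 0) is fully clamped; the top face receives a
  uniform prescribed displacement — normal for compression, tangential
  for shear — with the remaining components free;
* apparent stress = reaction force over the full 25 mm² section;
  e_rel = 100·(σ/ε)/E_bulk and g_rel = 100·(τ/γ)/G_bulk with
  γ = tangential displacement / cell height and
  G_bulk = E/(2(1+ν)).

E_bulk cancels exactly (verified to solver tolerance), so the labels
depend only on geometry and the Poisson ratio, fixed at ν = 0.35 (a
typical thermoplastic such as ABS). Displacement control is the
default because it is the better-conditioned formulation; a
force-controlled variant (25 N distributed over the top-face material
nodes by tributary area, strain read from their mean displacement) is
provided and agrees in the uniform-column case.

Voxels not 6-connected to a component touching both the clamped and
loaded faces are masked out before assembly — they carry no load and
would make the system singular. If no spanning component exists the
modulus is 0 with a `disconnected` flag.

The system is solved by conjugate gradients with a diagonal
preconditioner to a relative residual of 1e-8; the solve is seedless
and deterministic. Analytic anchors: a full cube at ν = 0 gives
e_rel = 100 %, a column covering fraction f of the cross-section gives
e_rel = 100·f %. The clamped-cube apparent shear modulus has no
closed form (free side faces), so it is checked by self-convergence
under grid refinement instead.

Default label resolution is 32 × 32 × 20, the same grid the CNN sees;
the resolution is a parameter (64 × 64 × 40 is supported) and the
discretization error shows up only as a slight systematic thickening
of thin struts, which affects labels and inputs coherently. Absolute
agreement with a body-fitted tetrahedral FEM at finer resolution is
not claimed — the labels are a self-consistent ground truth for the
learning problem, not a certified material datasheet.

## Augmentation

Six cumulative strategies expand a base of n lattices to n, 6n, 12n,
18n, 24n and 34n records (20 → 20/120/240/360/480/680):

1. the base;
2. + in-plane rotations about z at 15°, 30°, 45°, 60°, 75°;
3. + a zoom-in of every strategy-2 record (central crop of side
   32/factor, default factor 1.25, resampled back);
4. + vertical (row) flips of the 6n non-zoomed records;
5. + horizontal (column) flips of the 6n non-zoomed records;
6. + 3D rotations of the base about x and y at the same five angles
   (nearest-neighbour resampling in physical coordinates, honouring
   the anisotropic voxel size).

Flips are in-plane mirrors, never z-stack reversals. Interpolating
transforms re-binarize at 0.5 with ties → material, the downscaler's
rule. In-plane rotations keep the 32 × 32 footprint fixed (material
crossing the frame is lost, exposed corners are void): this preserves
the material fraction of centered geometry and makes quarter-turns
exact permutations, both of which are tested. For the 3D rotations the
frame-overlap fraction of a rotated full cube is ≈0.83 at 45°, the
geometric maximum loss; the tests compare against a dense-sampling
oracle of exactly this quantity.

Labels are copied unchanged from the source lattice. For rotations and
flips this is principled (the clamped-compression label is not exactly
rotation-invariant, but the error is second-order); for zoom it is a
modelling convention, not physics — elastic moduli are not scale
independent once strut slenderness changes. The convention keeps the
training signal consistent and is documented here as a known caveat.

## Network and training

Input is the (32, 32, 20) binary occupancy tensor. The architecture is
a three-block bottleneck: conv(16, 3³) → maxpool 2×2×2 → batchnorm →
dropout 0.3, conv(32) → same, conv(64) → maxpool 2×2×1 → batchnorm →
dropout, then flatten → dense 32 → dense 64 → dense 3. The third pool
keeps the z dimension (20 → 10 → 5) positive. Convolutions use ReLU,
dense layers leaky ReLU (slope 0.3, the historical framework default),
linear output head. Spatial shapes are walked and validated at build
time.

The network, its gradients and the Adam optimizer are implemented
directly on numpy (float32, sum-of-27-shifted-matmuls convolution);
gradients are verified against central finite differences and the
convolution against an independent correlation oracle.

Targets are min-max scaled to [0, 1] over the training split; training
minimizes MSE on that scale (reported "scaled MSE in %" = MSE × 100).
Validation records — round(0.3 · base-count), i.e. 6 for a 20-lattice
base — are drawn at random from the full augmented pool, which
reproduces the 70/30 split of the untransformed library for strategy 1
and permits source-lattice leakage for strategies 2–6 (the pool is the
sampling frame by design; holding out whole source lattices would be
the stricter alternative and can be done by passing explicit splits).
Defaults: Adam at lr 1e-3, batch 8, 200 epochs, best-validation
checkpoint; optimizer settings are unremarkable and configurable.

## Evaluation

Per-output MAE is computed on the original % scale; the **global MAE**
is the arithmetic mean of the three (an exact identity, tested);
scaled MSE uses the training scaler. `run_experiment` trains one
network per strategy and evaluates all of them on the 8 held-out test
lattices; with fixed seeds the reports are byte-identical across
reruns.

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script run the full pipeline at
sizes chosen to keep a complete desk run comfortable: label resolution
32 × 32 × 20, rasterization at 160 px (1440 px exercised where the
contract is about 1440 specifically), strategy-1 training for 120
epochs and strategy-6 for 12 epochs (similar optimizer-step budgets:
the point of the comparison is the augmentation recipe, not the epoch
count), memorization checks at 600 epochs on 5 records with the
best-checkpoint weights. These are package choices, recorded here
once; all of them are parameters.

## Known limitations

* The synthetic library emulates the *diversity* of a hand-designed
  CAD collection, not any specific published geometry; headline error
  numbers obtained on it characterize this pipeline on this library
  and transfer to other libraries only qualitatively.
* Labels inherit voxel discretization bias (thin features thicken);
  label and input share the representation, so the learning task
  remains well posed.
* The homogenizer is linear-elastic: no large strains, plasticity,
  contact, or stress-concentration fields.
* Grayscale (anti-aliased) slices are deliberately out of scope; the
  whole pipeline is binary end to end.
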