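# Methods

## Mechanical model of the cell-file cross-section

The modeled domain is an idealized 2D cross-section of a file of root
epidermal cells: an outer periclinal wall facing the organ surface, an
inner periclinal wall, and anticlinal walls shared between neighbors.
Default geometry (all configurable): 5 cells of 20 × 20 μm, outer wall
0.5 μm thick, anticlinal and inner walls 0.3 μm. Published root-epidermis
geometries motivate these orders of magnitude but fix no exact values; the
package's mechanical conclusions are relative trends (ratios and signs),
which are insensitive to the absolute dimensions within a realistic range.

A *vertex* is the intersection of an anticlinal wall midline with a
periclinal wall midline — the cross-sectional trace of a 3D geometric
edge. Softening divides the elastic modulus by a factor f ≥ 1 inside a
disc of radius r around each vertex; by default only outer-side vertices
are softened (the edges where anticlinal walls meet the outer wall), with
`sides="inner"|"both"` available, and the disc is measured from the
midline intersection. Elements belong to the softened region iff their
centroid lies in a disc — an unambiguous partition.

### Discretization and solver

- Bilinear quadrilaterals on a boundary-conforming tensor grid. The
  geometry is rectilinear, so the mesh is geometrically exact; at least
  two elements span every wall thickness.
- Plane strain by default (the cells are elongated normal to the
  section); plane stress by flag.
- The volumetric part of the strain-displacement operator is evaluated at
  the element centroid (mean dilatation / B-bar). At ν = 0.45 a fully
  integrated bilinear quad locks volumetrically; uniform reduced
  integration would instead need hourglass stabilization. Selective
  reduced integration avoids both while preserving the patch test.
- Turgor (default 5 bar = 5 × 10⁵ Pa) acts as a dead load on every
  lumen-facing wall segment of the undeformed geometry, consistent with a
  small-strain linear analysis: each boundary edge of length L
  contributes a force P·L along its lumen-to-wall normal, split equally
  between its nodes. A flag restricts pressurization to chosen segments.
- The inner periclinal wall is fully constrained (all displacement
  components of its nodes fixed).
- Sparse LU factorization (deterministic); the relative residual must be
  ≤ 1e-8 and a one-norm condition estimate guards against statically
  underdetermined inputs, which raise an explicit rigid-body-mode error
  rather than returning garbage.
- Unit system: lengths in μm, stresses in Pa, unit out-of-plane
  thickness. This is internally consistent for linear elasticity and
  yields displacements directly in μm; `bar` values in configs are
  converted to Pa at the interface.

### Validation

- Pressurized thick-walled ring (quarter-annulus with symmetry
  constraints) against the Lamé plane-strain closed form: 0.0035%
  displacement error at 32 radial elements; observed convergence order
  2.0.
- Constant-stress patch test on a distorted mesh: exact to 1e-10.
- Single-element stiffness against an independent symbolic integration of
  the B-bar formulation.
- Equilibrium, load linearity, translation objectivity, and rigid-body
  mode counts as property tests.

### Readouts

The distension readout is the maximum outward-normal (vertical)
displacement of the exterior outer-wall surface; the mean over the same
node set is reported alongside, since no specific metric is canonical.
Stress relocation is the change, relative to the f = 1 baseline on the
same mesh, of the area-weighted mean maximum principal stress σ₁ in the
vertex region and in the outer periclinal face region (outer elements not
tagged as vertex); area weighting makes the means mesh-size independent.
Displacement magnitudes are linear-elastic extrapolations (tens of μm at
f = 10) and are interpreted only as trends, never as predicted strains.

The production sweep uses `target_h = 0.075 μm` (~2.1 × 10⁴ elements),
at which successive refinement changes the readouts by well under 2%.

## Synthetic confocal stacks

Cells are axis-aligned boxes tiling a block inside an exterior margin, so
faces and edges are analytic and every statistic has exact ground truth;
this deliberately trades morphological realism for verifiability. Default
voxel size 0.1 × 0.1 × 0.3 μm (confocal-like anisotropy).

Puncta emulate the membrane-proximal vesicles measured by immuno-EM:
diameters are truncated-normal with mean 150 nm, SD 35 nm; membrane
distances truncated-normal with mean 93 nm, SD 36 nm. A punctum targets
the edge tube with probability `edge_fraction` (the free knob: 0.9 for
edge-clustered populations, 0 for dispersed controls); edge puncta are
placed uniformly along an edge chosen proportionally to length, then
displaced inward so their distance to each of the two faces meeting at
the edge equals the sampled membrane distance. Remaining puncta are
uniform in the cell volume. Recorded compartments (edge / face /
interior) come from classifying the final centers against the analytic
geometry with a 0.3 μm edge-tube radius (≈ 2 punctum diameters), so the
stored truth is exactly what a geometric classifier recovers.

Rendering: each punctum is an anisotropic Gaussian whose per-axis σ
combines the physical diameter (as FWHM) with the PSF σ = (0.08, 0.08,
0.25) μm in quadrature, normalized to a photon budget (default 5,000
integrated counts per punctum over a background of 10); optional membrane
signal paints label-boundary voxels. Noise is Poisson on signal +
background followed by additive Gaussian read noise (SD 2), from a single
seeded generator stream — fixed seed gives byte-identical stacks.

Default density is 150 puncta per cell, consistent with edge compartments
dense enough to outline individual cells in projections.

What the generator does *not* emulate: realistic PSFs (no Gibson–Lanni),
curved or segmented cell shapes, cytoplasm/vacuole intensity structure,
photobleaching, or depth-dependent attenuation. Passing recovery tests
therefore shows that the statistics measure what they claim on data whose
truth is known — not that segmentation or detection would succeed on real
root images.

## Enrichment statistic

For each cell, three consecutive 2-μm sections are cut inward from the
cell's outer surface (the face nearest the top of the volume, the
stand-in for the organ surface). Within a section, voxels are partitioned
by their full-3D Euclidean distance to the plasma membrane — computed
from the cell's complete boundary with anisotropic voxel sampling, not
slice-wise — into outer border (0–1 μm), inner border (1–2 μm), and
interior. Relative enrichment is the compartment mean divided by the
section mean, so the voxel-weighted mean over compartments is exactly 1
for any image and the statistic is invariant to intensity scaling. Empty
compartments (e.g. the interior of a section whose voxels are all within
2 μm of the membrane — always true of the outermost section) are reported
as missing, never as zero.

The ANOVA stage is a two-way fixed-effects model, compartment ×
treatment, with cells as the replicate unit: section values are averaged
per (cell, compartment) before the fit, and a Tukey HSD post hoc compares
all group pairs. The replicate-unit choice is stated in the report
because the original figure legend names only the test. Designs with
empty factor combinations are rejected with the missing pairs listed.

In edge-clustered stacks the membrane-proximal signal is confined well
within the 0–1 μm band; the 1–2 μm band receives only the far tail of the
PSF (≲ 0.3% of peak), so its systematic excess over the deep interior is
real but smaller than shot-noise variation at realistic cell counts. The
strict three-band ordering is therefore asserted on noise-free renders,
while noisy-data tests assert what is statistically identifiable: outer
elevation, its absence in dispersed controls, and the interaction term.

## Colocalization and the specificity test

Signal masks are `intensity > mean(background) + k·SD(background)` with
k = 1 or 2 and background taken from exterior (unlabeled) voxels by
default. Reciprocal colocalization is voxel-based Manders overlap per
cell (|A∩B|/|A| and |A∩B|/|B|), with an object-based mode (fraction of
discrete puncta touching the other mask) as an alternative readout;
empty-mask fractions are reported missing. Because ~2.3% of
noise-only voxels exceed the k = 2 threshold by chance, planted-overlap
recovery is validated with bright puncta (20,000 photons) so that true
signal dominates the masks; this SNR condition is part of the emulated
two-channel experiment and is reported with it.

Fisher's exact test enumerates all 2×2 tables with the observed margins;
one-sided p-values sum the hypergeometric tail, and the two-sided p sums
probabilities of tables no more probable than the observed one
(minimum-likelihood rule, stated in the output). On the line-count table
(16, 13; 0, 26) both one- and two-sided values are ≈ 2.3–2.5 × 10⁻⁶.

## Numerical and design notes

- Geometry, meshing, and the FEM contain no randomness; sweeps are
  byte-reproducible.
- Truncated-normal sampling uses rejection at zero (and at the half-cell
  inset for membrane distances); truncation bias at the default
  parameters is ≪ 1 SE.
- Distances to the periphery are measured to the nearest membrane-voxel
  center, which understates analytic distances by up to half a voxel
  diagonal; comparisons against closed forms use tolerances of one voxel
  diagonal.
- Degenerate inputs fail loudly: self-intersecting wall geometries,
  over-coarse meshes, unconstrained systems, shallow cells, empty factor
  combinations, and degenerate contingency margins all raise or warn
  explicitly.

## Limitations

Small-strain linear elasticity with dead pressure loads cannot predict
absolute deformations at 3–10-fold softening (reported distensions are
linear extrapolations), and the 2D section cannot capture longitudinal
edge effects; conclusions are restricted to orderings and signs, which
are mesh-converged and parameter-robust. The image statistics are
validated on geometrically ideal cells; applying them to segmented real
volumes requires label images of comparable quality as input.
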