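# Methods

## Density model

A reconstruction is treated as a piecewise-linear cable: a forest of
vertices (position μm, radius μm, compartment label) connected by
straight edges. Radii never enter the density — the quantity binned is
1D cable *length*, not membrane area or volume — so the model assumes
the tracing's point spacing is fine enough that straight segments
approximate the neurite path.

The sampling lattice covers the axis-aligned bounding box of **all**
loaded cells (after alignment), with per-axis voxel counts
N_j = ⌈E_j / l_j⌉ for box extent E_j and cuboid edge l_j. The ceiling
makes the lattice overshoot the tight box by up to one voxel per axis;
the lattice's outer box, not the tight box, defines "inside the grid".
A degenerate extent (E_j = 0, e.g. a planar cell) still gets one voxel.

Per neuron, each voxel receives the *exact* length of the cable inside
it. Every segment is clipped to the lattice's outer box by parametric
slab intersection (Liang–Barsky style), then cut at every internal
lattice plane it crosses; each resulting sub-interval lies in exactly one
voxel and deposits its length there. Summing sub-intervals telescopes to
the clipped segment length, which gives the conservation guarantee the
test suite asserts at 1e-9 relative: the voxel sums equal the in-grid
cable length. No Monte-Carlo or midpoint approximation is involved
(Monte-Carlo appears only as an independent oracle in tests).

Two per-neuron normalizations are provided behind `norm_mode`:

- `total_length` (default): voxel length / total cable length of the
  neuron. A fully contained cell's field sums to exactly 1; densities
  are dimensionless fractions. This is the default because it is the
  normalization in the combined-density formula below.
- `voxel_volume`: voxel length / (l₁·l₂·l₃), units μm⁻², useful when
  absolute cable packing matters.

Multiple neurons combine as the voxelwise sum S(B) = Σᵢ |B_i| over the
n neurons, rescaled by its grid-wide maximum m = max_B S(B). The sum
runs over the neurons i = 1..n; the definition of m as the maximum of
the per-voxel sum is what makes the combined field peak at exactly 1 and
live in [0, 1] (IEEE division x/x is exact, so "exactly" is literal).

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| cuboid_size l | μm | (50, 50, 50) | ~ one cortical minicolumn width; coarse enough that single-cell fields are not mostly empty |
| norm_mode | — | total_length | see above |
| min_density_pct | % of peak | 0 | keep every voxel with any cable |
| iso average / deviation | % of peak | 50 / 10 | mid-density band; both refer to the normalized field (max = 1) |
| blur kernel | voxels | Gaussian σ = 1, 5³, sum 1 | softens the blocky voxel raster for display |
| colors | RGB | blue → red | two-color linear coding of [0, 1] |

## Alignment and compartment filtering

Alignment to a consensus geometry is a **pure translation** moving each
cell's soma centroid (mean of its soma vertices; first root vertex as a
logged fallback) onto the consensus reference soma. No rotation or
scaling is attempted — nothing in the data model constrains cell
orientation reliably. Consequently all cable lengths and pairwise
distances are invariant under alignment.

The compartments present in a consensus scene act as a whitelist applied
before density computation (logged when it drops anything); an explicit
exclude list can be given as well. Filtering removes vertices and their
incident edges, so children of removed vertices become new roots.

Two edge-labeling conventions coexist deliberately: `total_length` with
an include-set counts an edge only when *both* endpoints are included
(so a soma→dendrite edge never leaks into a dendrite-only length), while
`Morphology.edge_compartments` labels each edge by its *child* vertex —
the SWC convention — for uses that need one label per edge. In the
density path the two agree, because filtering happens on vertices before
any length is computed.

## Numerical choices

- Voxels are half-open along internal boundary planes; a segment lying
  exactly in such a plane is credited to the higher-index voxel. Each
  sub-interval's voxel is identified by its midpoint, which implements
  this tie-break automatically. The effect is measure-zero but makes
  results deterministic.
- Edge sums run in file order in double precision; per-neuron fields are
  computed independently per cell and combined in sorted file order.
  Batch outputs are therefore byte-identical for any worker count — the
  partition-independence contract the suite enforces.
- Zero-length segments (duplicate points, single soma points) deposit
  nothing; a cell whose total length is 0 yields an all-zero field with
  a warning rather than NaN.
- Blurring convolves with reflective boundaries (constants are fixed
  points). The maximum of a normalized field may drop below 1; it is
  **not** re-normalized, only logged, so blur never invents density.
- `make_grid` computes ⌈E_j/l_j⌉ on the float quotient; SWC and OBJ
  writers print floats with `repr` (shortest exact round-trip), which
  makes write→read→write byte-stable and round-trips exact to the
  double.
- Marching cubes samples the field at voxel centers, so meshes cannot
  extend past the outer half-voxel shell. The triangulation uses the
  Lewiner 256-case tables as implemented by scikit-image (ambiguous
  cases resolved consistently; orientation follows descending gradient);
  vertices are welded at 1e-9 μm and zero-area triangles (< 1e-12 μm²)
  dropped. Watertightness is asserted on the analytic sphere fixture,
  not claimed for arbitrary fields.
- Isosurface band endpoints (average ± deviation)/100 are clamped into
  the open interval (0, 1); an empty band after clamping yields no
  meshes, and zero deviation collapses the pair to a single mesh.

## File-format dialects

SWC: 7 columns `id type x y z radius parent`, `#` comments; codes
1/2/3/4 map to soma/axon/dendrite/apical, 0 and ≥ 5 to `custom-N`
(written back as N). Neurolucida XML and ASC are read as the subset
needed here — trees (nesting = branching), points with diameter `d`
(halved to radius on import), and named contours; markers, spines and
image stacks are skipped with a logged count. A missing or corrupt XML
declaration is repaired (declaration prepended, multiple roots wrapped)
before parsing fails. Both dialects carry one compartment label per
tree, so per-point compartment changes inside a tree are representable
only in SWC — a documented dialect limitation. The `.dat` binary
container is rejected as unsupported. DAT aside, detection is by
extension, then content sniffing.

## Synthetic generator

The fixtures emulate the *geometric* situations the pipeline must handle
— a straight cable (known length, box, per-voxel masses), a Y-tree whose
per-slab masses along y have a closed form, seeded random arbors (PCG64;
same seed ⇒ byte-identical files) with soma/axon/dendrite labels, a
layered consensus scene with L1–L6 and barrel contours, and an analytic
radial field for isosurface checks. They do **not** emulate the
statistics of real interneuron classes: no realistic branch-angle or
segment-length distributions, no tortuosity, no reconstruction noise or
z-shrinkage. Passing tests therefore demonstrate correctness of the
geometry/accounting machinery on exactly representable inputs, not
robustness to tracing artifacts.

## Problem sizes

The test suite and the acceptance script run on deliberately small
inputs — random arbors of depth 3 (tens of vertices), 20³ isosurface
grids, 10⁵-sample Monte-Carlo clipping oracles over a few hundred
segment/box pairs — sizes at which every analytic oracle is exact and
the whole suite completes in seconds. The algorithms themselves carry no
size assumptions; grids are limited only by memory (8 bytes per voxel).

## Known limitations

- Alignment is translation-only; differently oriented cells are not
  registered.
- Densities are cable-length based; diameter-weighted (volume/surface)
  densities are out of scope.
- Arbitrary-direction projection is 1D only; 2D rasters exist for the
  three coordinate planes.
- No interactive 3D display or animation export; rendering is static
  figures (PNG/JPEG/TIFF/GIF) plus OBJ meshes.
- The Neurolucida readers target the tree/contour subset described
  above, not any specific vendor schema version.
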