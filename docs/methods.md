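# Methods

This note documents the models, conventions and numerical choices behind
`voromem`, what the synthetic bilayer generator does and does not emulate,
and the package's known limitations.

## Scope and conventions

- The membrane is assumed to be a single flat-to-gently-curved sheet whose
  normal is the z axis and which is not split across the z periodic
  boundary. Vesicles and strongly curved membranes are out of scope.
- Internal length unit is the nanometre everywhere. PDB input (Angstrom) is
  divided by 10 at the boundary; XTC/TRR are read and written in their
  native nm without unit conversion.
- Boxes must be orthorhombic; a triclinic box raises an explicit
  unsupported-box error.
- Atom and lipid indices are 0-based internally. NDX files and the
  human-readable TXT/XML exports use 1-based ids.
- Each lipid species is described by a *key atom* (tessellation generator;
  default the phosphate "P") and a list of candidate terminal tail atoms
  (orientation vectors). Definitions come from a config file
  (`RESNAME: head=P tails=A,B`) or the built-in defaults for common
  phosphatidylcholines/-ethanolamines.

## Leaflet detection

**Orientation method.** Orientation vector = head position − mean(tail
positions); a positive z component labels the lipid `upper`. An exactly
horizontal vector ties to `upper` with a warning. Cost O(n); fooled by
lipids whose conformation inverts the head–tail z-order.

**Position method.** One global polynomial surface z = Σ_{a+b≤d} c_ab x^a
y^b is least-squares fitted (`numpy.linalg.lstsq`) to all lipid key atoms of
the frame; the sign of each key atom's residual labels the lipid. Default
degree d = 2 — enough for the gently curved membranes in scope; exposed as
`--poly-degree`. An `all_atoms` switch fits every lipid atom instead of the
key atoms only. A residual of exactly zero falls back to the orientation
rule for that lipid. The fit is to one shared midsurface rather than
per-leaflet iterated surfaces; monomials are evaluated on raw coordinates
(xy wrapping is irrelevant to the classification since both leaflets see
the same surface). Underdetermined fits (fewer points than (d+1)(d+2)/2
monomials) and xy-collinear designs raise errors rather than guessing.

## Periodic tessellation

Generators (lipid key atoms, plus inclusion atoms) are wrapped into the
primary box. Periodicity is realized by *ghost replication*: image copies
shifted by (±lx, ±ly) combinations that land within a margin of the box are
appended, and a Euclidean Voronoi diagram / Delaunay triangulation is
computed on the extended set with Qhull (scipy). With a sufficient margin
every primary generator is an interior point, its cell is finite and equals
its cell in the true periodic diagram, and cell areas tile the box exactly
(verified to ~1e−15 relative in practice). Defaults: full 9-image
replication below 100 generators, margin max(lx, ly)/2 above.

- Cell areas are computed with the shoelace formula on the
  counter-clockwise-ordered Voronoi vertices.
- Adjacency comes from shared Voronoi ridges with image endpoints mapped
  back to their source generators; ridges shorter than 1e−9 nm (degenerate
  cocircular configurations, e.g. perfect lattices) are not adjacency.
- Exactly coincident generators are perturbed by 1e−9 nm in a
  deterministic direction derived from the generator index (Knuth
  multiplicative hash), with a warning.

**Inclusions.** Atoms of residues not matching any lipid definition whose z
lies within [min(z_head) − m, max(z_head) + m] of a leaflet's key atoms are
inserted as extra generators for that leaflet (slab margin m, default
0.5 nm, `--slab-margin`). All atoms in the slab are inserted, not one per
residue. Inclusion cells take part in the area partition but are excluded
from all lipid statistics.

## Metrics

**APL** of a lipid = the area of its generator's Voronoi cell. On a perfect
lattice this is exactly box_area/n; with inclusions present the lipid areas
sum to less than the box area while the full partition still tiles it.

**Membrane thickness** of a lipid = |z_key − z*| where z* is the opposite
leaflet's key-atom surface interpolated barycentrically at the lipid's
(x, y), on the opposite leaflet's Delaunay triangulation built over fully
replicated images (which guarantees every wrapped query point is contained).
Barycentric interpolation reproduces affine surfaces exactly, so flat and
tilted constructions give exact thicknesses. Point location uses Qhull's
`find_simplex` (deterministic; barycentric coordinates below 1e−12 are
snapped to zero). Note that an affine field cannot be globally consistent
with periodic images, so exactness at the box boundary holds only for
fields that are themselves periodic (e.g. flat surfaces). Thickness is a
vertical distance, not a distance along a local normal — consistent with
the flat-membrane scope.

**Neighborhoods** are edge-sharing Voronoi neighbors grouped by residue
name, with inclusion neighbors counted separately.

**Aggregation** is the per-frame arithmetic mean over a selection; frames
with an empty selection yield NaN (serialized as `nan` in XVG), never zero.

## Selections

AND-conjunctions of conditions over `resname`, `leaflet`, `apl`,
`thickness` and `neighbor_count[RESNAME]` with operators
`== != < <= > >= in` (grammar in the `select` module docstring). OR is
expressed as multiple queries unioned by the caller. Selections are
re-evaluated every frame (dynamic membership); `--freeze-frame` pins
membership to one frame instead. Unknown fields and residue names are
rejected before evaluation, with the character position for syntax errors.

## Synchronized comparison

Trajectories are aligned on a shared integer axis: aligned index k of a
trajectory with (offset, stride) maps to local frame offset + k·stride;
offsets may be negative and out-of-range mappings become missing values.
A time-based offset convenience converts ps to the nearest frame with
ties rounding half-down.

## Rendering

Voronoi maps are rasterized with Pillow (deterministic byte-for-byte):
cells filled via a piecewise-linear color scale over clamped normalized
values, black borders, selected cells in blue, inclusion cells in a
reserved neutral grey, a fixed-size legend top-left and the leaflet label
top-right. Channel values round half-up. The LOCS scale is a 256-entry
luminance-optimized table generated from black→blue→magenta→orange→yellow→
white control points placed at their own luminances, so perceived
brightness grows approximately linearly; it is this package's own pinned
construction of a linear optimized color scale, not a copy of any
published table. Heated-object is black→red→yellow→white, rainbow
blue→cyan→green→yellow→red. Default vmin/vmax are the per-frame min/max
of the mapped metric unless overridden. Time-series plots go through
matplotlib (Agg).

## Synthetic bilayer generator

The generator builds two leaflets of 3-atom point-lipids (head "P" at
±thickness/2 around the box-center midplane; tails "T1"/"T2" at 0.5 and
1.0 nm towards the midplane) on an nx×ny lattice, with:

- `spacing` (default 0.8 nm → APL 0.64 nm², a realistic fluid-phase
  phosphatidylcholine value) and `thickness` (default 4.0 nm, a typical
  phosphate-to-phosphate distance);
- independent Gaussian xy and z jitter per lipid per frame (whole-lipid
  displacement, so orientations stay intact);
- optional quadratic curvature bulge in x (amplitude at the box center,
  zero at the edges — inside the degree-2 model class of the position
  method by construction);
- a seeded choice of *inverted* lipids (tails point outward, head stays at
  the leaflet position) that fool the orientation method but not the
  position method;
- an optional cylindrical inclusion (resname PROT): rings of atoms at the
  lower-leaflet, midplane and upper-leaflet heights, with lattice sites
  inside the cylinder radius carved out.

All randomness comes from `numpy.random.default_rng(seed)` (PCG64); the
same spec produces byte-identical PDB/XTC/TRR/NDX/TSV outputs. Ground
truth (leaflet label, inverted flag) is recorded per lipid.

What the generator does **not** emulate: realistic acyl-chain
conformations, area/thickness correlations, undulation spectra, lipid
mixing dynamics or protein shapes. Passing tests therefore demonstrate the
geometric and statistical correctness of the pipeline (tessellation,
interpolation, classification, I/O), not force-field-level realism of any
membrane observable.

## Numerical choices and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `--poly-degree` | 2 | midsurface polynomial degree |
| `--slab-margin` | 0.5 nm | inclusion z-slab beyond the key-atom range |
| replication margin | 9 images (n < 100) else max(lx, ly)/2 | ghost width |
| duplicate epsilon | 1e−9 nm | coincident-generator perturbation |
| ridge cutoff | 1e−9 nm | minimum Voronoi edge length for adjacency |
| barycentric epsilon | 1e−12 | snap-to-zero for containment |
| XTC precision | 1000 | 0.001 nm coordinate quantum on disk |

XVG payloads are printed with 10 significant digits; XML exports serialize
floats with `repr` so they re-parse exactly. TXT column order is fixed:
lipid id, resname, leaflet, APL (nm²), MT (nm), lipid-neighbor count,
inclusion-neighbor count, per-resname neighbor summary. The XML schema is
one `<frame index time>` element with `<lipid id resname leaflet apl
thickness lipid_neighbors inclusion_neighbors neighbors>` children.

## Problem sizes used in the checks

The self-checks run on deliberately small systems — tessellations of
16–256 generators, bilayers of 32–512 lipids, trajectories of 1–30
frames — chosen so the whole suite exercises every code path in seconds
while the verified properties (exact tiling, affine exactness, label
recovery, bit-level determinism) are size-independent.

## Known limitations

- Triclinic boxes, vesicles and membranes split across the z boundary are
  rejected or unsupported by construction.
- Thickness uses a vertical metric; for visibly curved membranes it
  overestimates the normal-direction thickness by 1/cos(tilt).
- The TRR writer stores single precision (the common GROMACS default);
  double-precision TRR files are read but rewritten as single.
- One shared midsurface is fitted for both leaflets; strongly asymmetric
  membranes may warrant per-leaflet surfaces, which are not implemented.
- Whether selections should be dynamic or frozen is workload-dependent;
  both are offered and neither is claimed canonical.
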