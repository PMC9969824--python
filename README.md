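# voromem

Voronoi-based analysis of lipid bilayer simulations: leaflet detection,
area per lipid (APL), membrane thickness (MT), selections, multi-simulation
comparison and rendering — as a Python library with a streaming command line.

## The problem

Molecular-dynamics simulations of cell membranes are routinely summarized by
two observables: the **area per lipid**, the lateral area a lipid occupies in
its leaflet, and the **membrane thickness**, the vertical separation between
the two leaflets' head-group surfaces. Both respond to phase changes, protein
binding and raft formation. `voromem` computes them per lipid and per frame
for GROMACS-style trajectories (PDB topology, XTC/TRR coordinates, NDX
groups) of flat or gently curved bilayers.

## Method

Per frame, the pipeline runs five steps per leaflet:

1. **Leaflet detection.** Either by lipid *orientation* — the sign of the
   z-component of the head-minus-mean-tail vector — or by *position*: a
   polynomial midsurface z = Σ c_ab x^a y^b (total degree d, default 2) is
   fitted to all lipid key atoms by least squares and each lipid is labeled
   by the sign of its key atom's residual. The position method costs
   O(n·d²) and is robust to lipids whose conformation inverts the
   head–tail order.
2. **Periodic Delaunay triangulation** of the leaflet's key atoms
   (typically the phosphate P), realized by ghost-replicating generators
   across the periodic box and triangulating the extended set (Qhull).
3. **Inclusion insertion**: non-lipid atoms (e.g. protein) inside the
   leaflet's z-slab become extra generators, so lipid cells are not
   inflated around embedded molecules. The triangulation also provides the
   local MT: each lipid's key atom is projected onto the opposite leaflet's
   triangulated surface and the interpolated vertical distance
   |z_key − z*| is exact for planar and affine opposite surfaces.
4. **Voronoi diagram** as the dual of the Delaunay triangulation; cells of
   primary generators are finite and tile the box exactly.
5. **APL** = the area of a lipid's Voronoi cell (shoelace formula);
   neighborhoods are the edge-sharing cells, counted by lipid type.

Selections (`resname == DPPC and apl > 0.6 and neighbor_count[DPPC] >= 4`),
frame-synchronized comparison of several simulations, XVG/TXT/XML exports
and deterministic PNG Voronoi maps (rainbow, LOCS, heated-object,
linear-grey color scales) sit on top.

## Worked example

Everything runs on synthetic bilayers with recorded ground truth — no
external data needed:

```sh
voromem synth --nx 8 --ny 8 --spacing 0.8 --thickness 4.0 \
    --jitter-xy 0.05 --jitter-z 0.05 --n-frames 20 --seed 7 --out sim
voromem analyze --topology sim.pdb --traj sim.xtc --out results \
    --stat mean_apl --stat mean_thickness
voromem render --topology sim.pdb --traj sim.xtc --frame 0 \
    --metric apl --scale locs --out apl_map.png
```

`results/series.xvg` then holds four per-frame columns. For this system
(64 lipids per leaflet on a 0.8 nm lattice, σ = 0.05 nm jitter) the first
rows are:

```
0 0.6400000191 0.6400000191 3.995275148 3.995884339
1 0.6400000191 0.6400000191 3.976884843 3.975902871
2 0.6400000191 0.6400000191 4.004911284 4.005224422
```

i.e. mean APL of the upper and lower leaflet (0.64 nm² = box area / 64 at
the trajectory's single precision, because lateral jitter redistributes but
conserves area) and
mean MT per leaflet fluctuating around the constructed 4.0 nm. The Voronoi
map colors each cell by its APL on the luminance-optimized scale with the
legend top-left and the leaflet label top-right.

As a library:

```python
import voromem as vm

spec = vm.SynthSpec(nx=8, ny=8, spacing=0.8, jitter_z=0.05, seed=7)
system = vm.build_system(spec)
topo = vm.read_topology(...)          # or build from your own PDB
frame = system.frames[0]
assignment = vm.assign_by_position(frame, topo, degree=2)
metrics = vm.compute_frame_metrics(frame, topo, assignment)
print(metrics.table[["apl", "thickness"]].mean())
```

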