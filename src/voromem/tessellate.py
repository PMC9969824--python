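"""Periodic 2D Delaunay/Voronoi tessellation of a leaflet.

Periodicity is realized by ghost replication: generators are wrapped into
the primary box, periodic images within a margin of the box are appended,
and a Euclidean Voronoi diagram / Delaunay triangulation is computed on the
extended point set (Qhull via scipy).  Every primary generator is then an
interior point, so its Voronoi cell is finite and equals its cell in the
true periodic diagram; areas therefore tile the box exactly.  Image
neighbors are mapped back to their source generators for adjacency.

Non-lipid atoms lying in a leaflet's z slab ("inclusions", e.g. protein
atoms) can be inserted as extra generators so that lipid cell areas are not
inflated around embedded molecules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi

from .leaflets import LeafletAssignment
from .trajio import FrameData, Topology

logger = logging.getLogger(__name__)

LIPID = "lipid"
INCLUSION = "inclusion"

DUPLICATE_EPS = 1e-9  # nm; deterministic nudge for coincident generators
_RIDGE_LENGTH_TOL = 1e-9  # nm; degenerate (zero-length) Voronoi edges are not adjacency
DEFAULT_SLAB_MARGIN = 0.5  # nm


class TessellationError(Exception):
    pass


@dataclass(frozen=True)
class Generator:
    """One tessellation generator: a lipid key atom or an inclusion atom."""

    id: int
    kind: str  # "lipid" | "inclusion"
    xy: tuple[float, float]  # wrapped into [0, lx) x [0, ly)
    z: float
    lipid_id: int | None = None
    atom_id: int | None = None


@dataclass
class Tessellation2D:
    """Periodic Voronoi cells and Delaunay triangles over one leaflet."""

    generators: list[Generator]
    box: tuple[float, float]
    cells: list[np.ndarray]  # per generator: (k, 2) ccw vertex array
    areas: np.ndarray  # per generator, nm^2
    adjacency: list[set[int]]  # per generator: neighbor generator ids
    triangles: set[frozenset[int]]  # Delaunay triples mapped back to source ids
    # extended-point internals, kept for point location / interpolation
    ext_points: np.ndarray = field(repr=False, default=None)
    image_of: np.ndarray = field(repr=False, default=None)
    delaunay: Delaunay = field(repr=False, default=None)

    @property
    def n_generators(self) -> int:
        return len(self.generators)

    def lipid_cell_areas(self) -> dict[int, float]:
        """Map lipid_id -> Voronoi cell area (inclusion cells excluded)."""
        return {
            g.lipid_id: float(self.areas[g.id])
            for g in self.generators
            if g.kind == LIPID
        }


def wrap_xy(points: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Wrap xy coordinates into the primary box [0, lx) x [0, ly)."""
    lx, ly = box
    out = np.array(points, dtype=float, copy=True)
    out[:, 0] = np.mod(out[:, 0], lx)
    out[:, 1] = np.mod(out[:, 1], ly)
    return out


def replicate_periodic(
    points: np.ndarray, box: tuple[float, float], margin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Append periodic image points within ``margin`` of the primary box.

    Returns ``(extended_points, image_of)`` where ``image_of[k]`` is the
    index of the source point of extended point ``k``; the first ``n``
    entries are the primary points themselves.  With
    ``margin >= max(lx, ly)`` all 8 images of every point are present.
    """
    lx, ly = box
    if lx <= 0 or ly <= 0:
        raise TessellationError(f"box lengths must be positive, got {box}")
    if margin <= 0:
        raise TessellationError("replication margin must be positive")
    points = np.asarray(points, dtype=float)
    n = len(points)
    ext = [points]
    src = [np.arange(n)]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shifted = points + np.array([sx * lx, sy * ly])
            keep = (
                (shifted[:, 0] > -margin)
                & (shifted[:, 0] < lx + margin)
                & (shifted[:, 1] > -margin)
                & (shifted[:, 1] < ly + margin)
            )
            if np.any(keep):
                ext.append(shifted[keep])
                src.append(np.nonzero(keep)[0])
    return np.concatenate(ext), np.concatenate(src)


def _perturb_duplicates(points: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Nudge exactly coincident generators apart by a deterministic epsilon."""
    seen: dict[tuple[float, float], int] = {}
    out = points.copy()
    for i, (x, y) in enumerate(points):
        key = (float(x), float(y))
        if key in seen:
            # direction derived from the generator index (Knuth hash), so the
            # perturbation is reproducible run to run
            angle = 2.0 * math.pi * ((i * 2654435761) % 4294967296) / 4294967296.0
            out[i, 0] += DUPLICATE_EPS * math.cos(angle)
            out[i, 1] += DUPLICATE_EPS * math.sin(angle)
            logger.warning(
                "generators %d and %d coincide; perturbing %d by %g nm",
                seen[key],
                i,
                i,
                DUPLICATE_EPS,
            )
        else:
            seen[key] = i
    return wrap_xy(out, box)


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ccw_cell(vertices: np.ndarray, center: np.ndarray) -> np.ndarray:
    ang = np.arctan2(vertices[:, 1] - center[1], vertices[:, 0] - center[0])
    return vertices[np.argsort(ang)]


def tessellate_leaflet(
    generators: list[Generator],
    box: tuple[float, float],
    margin: float | None = None,
) -> Tessellation2D:
    """Build the periodic Voronoi diagram / Delaunay triangulation.

    ``margin`` controls ghost replication; by default the full 9-image set
    is used for small systems (n < 100) and ``max(lx, ly) / 2`` otherwise.
    Requires at least 3 generators not all collinear.
    """
    n = len(generators)
    if n < 3:
        raise TessellationError(f"need at least 3 generators, got {n}")
    lx, ly = box
    if margin is None:
        margin = max(lx, ly) if n < 100 else max(lx, ly) / 2.0
    pts = wrap_xy(np.array([g.xy for g in generators], dtype=float), box)
    pts = _perturb_duplicates(pts, box)

    ext_pts, image_of = replicate_periodic(pts, box, margin)
    try:
        vor = Voronoi(ext_pts)
        dela = Delaunay(ext_pts)
    except QhullError as exc:
        raise TessellationError(f"degenerate generator set: {exc}") from exc

    cells: list[np.ndarray] = []
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise TessellationError(
                f"generator {i} has an unbounded Voronoi cell; "
                "increase the replication margin"
            )
        verts = _ccw_cell(vor.vertices[region], pts[i])
        cells.append(verts)
        areas[i] = _shoelace(verts)

    adjacency: list[set[int]] = [set() for _ in range(n)]
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n and q >= n:
            continue
        if -1 not in rv:
            a, b = vor.vertices[rv[0]], vor.vertices[rv[1]]
            if np.hypot(*(a - b)) <= _RIDGE_LENGTH_TOL:
                continue  # degenerate edge (cocircular configuration)
        sp, sq = int(image_of[p]), int(image_of[q])
        if sp == sq:
            continue
        adjacency[sp].add(sq)
        adjacency[sq].add(sp)

    triangles: set[frozenset[int]] = set()
    for simplex in dela.simplices:
        if np.all(simplex >= n):
            continue
        src = frozenset(int(image_of[v]) for v in simplex)
        if len(src) == 3:
            triangles.add(src)

    return Tessellation2D(
        generators=generators,
        box=box,
        cells=cells,
        areas=areas,
        adjacency=adjacency,
        triangles=triangles,
        ext_points=ext_pts,
        image_of=image_of,
        delaunay=dela,
    )


def lipid_generators(
    frame: FrameData,
    topology: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
) -> list[Generator]:
    """Key-atom generators for the lipids of one leaflet."""
    lx, ly = frame.box[0], frame.box[1]
    gens: list[Generator] = []
    for lipid_id in assignment.lipid_ids(leaflet):
        lp = topology.lipids[lipid_id]
        x, y, z = frame.positions[lp.head_index]
        gens.append(
            Generator(
                id=len(gens),
                kind=LIPID,
                xy=(x % lx, y % ly),
                z=float(z),
                lipid_id=int(lipid_id),
            )
        )
    return gens


def insert_inclusions(
    frame: FrameData,
    topology: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    slab_margin: float = DEFAULT_SLAB_MARGIN,
) -> list[Generator]:
    """Lipid generators plus inclusion generators for one leaflet.

    Non-lipid atoms whose z coordinate lies within
    ``[min(z_head) - slab_margin, max(z_head) + slab_margin]`` of the
    leaflet's key atoms are inserted as inclusion generators.  Returns the
    combined generator list (lipids first).  Zero inclusions is valid.
    """
    gens = lipid_generators(frame, topology, assignment, leaflet)
    if not gens:
        return gens
    head_z = np.array([g.z for g in gens])
    z_lo, z_hi = head_z.min() - slab_margin, head_z.max() + slab_margin
    lx, ly = frame.box[0], frame.box[1]
    for atom_id in topology.non_lipid_atom_indices():
        x, y, z = frame.positions[atom_id]
        if z_lo <= z <= z_hi:
            gens.append(
                Generator(
                    id=len(gens),
                    kind=INCLUSION,
                    xy=(x % lx, y % ly),
                    z=float(z),
                    atom_id=int(atom_id),
                )
            )
    return gens
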