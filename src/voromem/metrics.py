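"""Per-lipid membrane metrics: area per lipid, thickness, neighborhoods.

APL is the area of a lipid's Voronoi cell in the 2D leaflet tessellation;
inclusion cells take part in the partition of the box but are excluded from
lipid statistics.  Membrane thickness is the vertical distance between a
lipid's key atom and the opposite leaflet's key-atom surface, interpolated
barycentrically on the opposite leaflet's periodic Delaunay triangulation
(exact for planar and affine opposite surfaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .leaflets import LOWER, UPPER, LeafletAssignment
from .tessellate import (
    DEFAULT_SLAB_MARGIN,
    INCLUSION,
    LIPID,
    Tessellation2D,
    insert_inclusions,
    replicate_periodic,
    tessellate_leaflet,
    wrap_xy,
)
from .trajio import FrameData, Topology

STATISTICS = ("mean_apl", "mean_thickness")

_BARYCENTRIC_EPS = 1e-12


class MetricsError(Exception):
    pass


@dataclass
class TimeSeries:
    """Named per-frame series on a shared x axis (frame index or time/ps)."""

    x: np.ndarray
    columns: dict[str, np.ndarray]
    xlabel: str = "Time (ps)"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            if len(col) != len(self.x):
                raise MetricsError(
                    f"column {name!r} length {len(col)} != x length {len(self.x)}"
                )
            self.columns[name] = col


@dataclass
class FrameMetrics:
    """Per-lipid metrics for one frame.

    ``table`` is indexed by 0-based lipid id with columns ``resname``,
    ``leaflet``, ``apl`` (nm^2), ``thickness`` (nm), ``neighbors`` (dict
    resname -> count), ``n_lipid_neighbors`` and ``n_inclusion_neighbors``.
    """

    frame_index: int
    time: float
    table: pd.DataFrame
    tessellations: dict[str, Tessellation2D] = field(default_factory=dict, repr=False)


def compute_apl(tess: Tessellation2D) -> dict[int, float]:
    """Voronoi cell area of each lipid generator, keyed by lipid id."""
    return tess.lipid_cell_areas()


def interpolate_surface_z(
    query_xy: np.ndarray,
    surface_xy: np.ndarray,
    surface_z: np.ndarray,
    box: tuple[float, float],
) -> np.ndarray:
    """Barycentric interpolation of z on the periodic Delaunay of a surface.

    The surface points are replicated over all 8 periodic images, so every
    wrapped query point falls inside some triangle.  Reproduces affine
    z-fields exactly.
    """
    if len(surface_xy) < 3:
        raise MetricsError("surface interpolation needs at least 3 points")
    lx, ly = box
    pts = wrap_xy(np.asarray(surface_xy, dtype=float), box)
    ext, image_of = replicate_periodic(pts, box, margin=max(lx, ly))
    ext_z = np.asarray(surface_z, dtype=float)[image_of]
    tri = Delaunay(ext)
    q = wrap_xy(np.asarray(query_xy, dtype=float), box)
    simplex = tri.find_simplex(q)
    missed = simplex < 0
    if np.any(missed):
        # tolerate points marginally outside due to round-off
        simplex2 = tri.find_simplex(q[missed], tol=1e-9)
        simplex[missed] = simplex2
        if np.any(simplex < 0):
            raise MetricsError("query point outside replicated triangulation")
    # barycentric coordinates from the simplex affine transform
    T = tri.transform[simplex]
    b2 = np.einsum("nij,nj->ni", T[:, :2, :], q - T[:, 2, :])
    bary = np.column_stack([b2, 1.0 - b2.sum(axis=1)])
    bary = np.where(np.abs(bary) < _BARYCENTRIC_EPS, 0.0, bary)
    verts = tri.simplices[simplex]
    return np.einsum("ni,ni->n", bary, ext_z[verts])


def compute_thickness(
    frame: FrameData,
    topology: Topology,
    assignment: LeafletAssignment,
) -> dict[int, float]:
    """Local membrane thickness for every lipid, keyed by lipid id.

    For each lipid the key atom is projected to (x, y); the opposite
    leaflet's key-atom surface z* is interpolated there and the thickness is
    ``|z_key - z*|``.  Both leaflets need at least 3 lipids.
    """
    heads = topology.head_indices
    head_pos = frame.positions[heads]
    box2 = (frame.box[0], frame.box[1])
    out: dict[int, float] = {}
    for leaflet, opposite in ((UPPER, LOWER), (LOWER, UPPER)):
        ids = assignment.lipid_ids(leaflet)
        opp_ids = assignment.lipid_ids(opposite)
        if len(ids) == 0:
            continue
        if len(opp_ids) < 3:
            raise MetricsError(
                f"{opposite} leaflet has {len(opp_ids)} lipids; "
                "thickness interpolation needs at least 3"
            )
        z_star = interpolate_surface_z(
            head_pos[ids, :2], head_pos[opp_ids, :2], head_pos[opp_ids, 2], box2
        )
        for lipid_id, z_interp in zip(ids, z_star):
            out[int(lipid_id)] = abs(float(head_pos[lipid_id, 2]) - float(z_interp))
    return out


def neighbor_profile(
    tess: Tessellation2D, topology: Topology
) -> dict[int, dict[str, object]]:
    """Edge-sharing Voronoi neighbors of each lipid, grouped by resname.

    Returns ``{lipid_id: {"by_resname": {resname: count}, "inclusion": k}}``.
    """
    resname_of = {g.id: topology.lipids[g.lipid_id].resname
                  for g in tess.generators if g.kind == LIPID}
    kind_of = [g.kind for g in tess.generators]
    out: dict[int, dict[str, object]] = {}
    for g in tess.generators:
        if g.kind != LIPID:
            continue
        by_resname: dict[str, int] = {}
        n_incl = 0
        for nb in tess.adjacency[g.id]:
            if kind_of[nb] == INCLUSION:
                n_incl += 1
            else:
                rn = resname_of[nb]
                by_resname[rn] = by_resname.get(rn, 0) + 1
        out[g.lipid_id] = {"by_resname": by_resname, "inclusion": n_incl}
    return out


def compute_frame_metrics(
    frame: FrameData,
    topology: Topology,
    assignment: LeafletAssignment,
    slab_margin: float = DEFAULT_SLAB_MARGIN,
) -> FrameMetrics:
    """Run the per-frame pipeline: tessellate both leaflets, APL/MT/neighbors."""
    box2 = (frame.box[0], frame.box[1])
    apl: dict[int, float] = {}
    neighbors: dict[int, dict[str, object]] = {}
    tessellations: dict[str, Tessellation2D] = {}
    for leaflet in (UPPER, LOWER):
        if len(assignment.lipid_ids(leaflet)) == 0:
            continue
        gens = insert_inclusions(frame, topology, assignment, leaflet, slab_margin)
        tess = tessellate_leaflet(gens, box2)
        tessellations[leaflet] = tess
        apl.update(compute_apl(tess))
        neighbors.update(neighbor_profile(tess, topology))
    thickness = compute_thickness(frame, topology, assignment)

    ids = sorted(apl)
    table = pd.DataFrame(
        {
            "resname": [topology.lipids[i].resname for i in ids],
            "leaflet": [assignment.labels[i] for i in ids],
            "apl": [apl[i] for i in ids],
            "thickness": [thickness.get(i, np.nan) for i in ids],
            "neighbors": [neighbors[i]["by_resname"] for i in ids],
            "n_lipid_neighbors": [
                sum(neighbors[i]["by_resname"].values()) for i in ids
            ],
            "n_inclusion_neighbors": [neighbors[i]["inclusion"] for i in ids],
        },
        index=pd.Index(ids, name="lipid_id"),
    )
    return FrameMetrics(
        frame_index=frame.frame_index,
        time=frame.time,
        table=table,
        tessellations=tessellations,
    )


def aggregate(
    frames: list[FrameMetrics],
    statistic: str,
    selection: set[int] | list[set[int]] | None = None,
    column_name: str | None = None,
    x_axis: str = "time",
) -> TimeSeries:
    """Per-frame arithmetic mean of a metric over a lipid selection.

    ``selection`` may be a fixed id set, a per-frame list of id sets (dynamic
    membership), or None for all lipids.  Frames where the selection is
    empty yield NaN, not zero.
    """
    if statistic not in STATISTICS:
        raise MetricsError(
            f"unknown statistic {statistic!r}; expected one of {STATISTICS}"
        )
    col = {"mean_apl": "apl", "mean_thickness": "thickness"}[statistic]
    xs = np.empty(len(frames))
    vals = np.empty(len(frames))
    for k, fm in enumerate(frames):
        xs[k] = fm.time if x_axis == "time" else fm.frame_index
        sel = selection[k] if isinstance(selection, list) else selection
        table = fm.table if sel is None else fm.table.loc[sorted(sel & set(fm.table.index))]
        vals[k] = float(table[col].mean()) if len(table) else np.nan
    name = column_name or statistic
    xlabel = "Time (ps)" if x_axis == "time" else "Frame"
    return TimeSeries(x=xs, columns={name: vals}, xlabel=xlabel)
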