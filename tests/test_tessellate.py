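"""Periodic tessellation: area conservation, adjacency, Delaunay property."""

import numpy as np
import pytest

from voromem.tessellate import (
    DUPLICATE_EPS,
    INCLUSION,
    LIPID,
    Generator,
    TessellationError,
    insert_inclusions,
    replicate_periodic,
    tessellate_leaflet,
)

from conftest import lattice_points, make_generators, system_topology


def min_image_dist(p, q, box):
    """Torus distance between two 2D points."""
    d = np.asarray(p) - np.asarray(q)
    d -= np.asarray(box) * np.round(d / np.asarray(box))
    return float(np.hypot(*d))


def torus_distances(samples, points, box):
    """Torus distance of each sample (m, 2) to each point (n, 2) -> (m, n)."""
    d = samples[:, None, :] - points[None, :, :]
    d -= np.asarray(box) * np.round(d / np.asarray(box))
    return np.hypot(d[..., 0], d[..., 1])


def bruteforce_adjacency(points, box, min_edge=1e-9):
    """Exact periodic Voronoi adjacency by bisector interval intersection.

    Pair (i, j) is adjacent iff some point equidistant (torus metric) to
    both is nearer to them than to every other generator image.  Along the
    perpendicular bisector line x(s) of i and an image of j, each condition
    "x at least as close to i as to image point q" is linear in s, so the
    shared Voronoi edge is the exact intersection of half-lines; the pair
    is adjacent iff the interval has positive length (> ``min_edge``, the
    same degeneracy cutoff the tessellation uses for zero-length ridges).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    lx, ly = box
    reach = np.hypot(lx, ly)  # |s| bound: a cell never extends past one period
    # constraint images over a 5x5 shift block (covers every image a point
    # within |s| <= reach of the primary box can see as nearest)
    shifts5 = [(sx, sy) for sx in range(-2, 3) for sy in range(-2, 3)]
    all_pts = np.concatenate(
        [points + np.array([sx * lx, sy * ly]) for sx, sy in shifts5]
    )
    block_of = {s: k for k, s in enumerate(shifts5)}
    shifts9 = [(sx, sy) for sx in (-1, 0, 1) for sy in (-1, 0, 1)]

    adjacency = [set() for _ in range(n)]
    for i in range(n):
        pi = points[i]
        row_i = block_of[(0, 0)] * n + i
        for j in range(i + 1, n):
            adjacent = False
            for sh in shifts9:
                pj = points[j] + np.array([sh[0] * lx, sh[1] * ly])
                d = pj - pi
                norm = np.hypot(*d)
                if norm == 0.0 or norm > reach:
                    continue
                mid = (pi + pj) / 2.0
                u = np.array([-d[1], d[0]]) / norm
                # dist^2(x(s), q) = s^2 + 2 s u.(mid - q) + |mid - q|^2:
                # closeness to pi vs q is  A s + C >= 0  with the terms below
                mq = mid - all_pts
                b = 2.0 * (mq @ u)
                c = (mq**2).sum(axis=1)
                row_j = block_of[sh] * n + j
                keep = np.ones(len(all_pts), dtype=bool)
                keep[[row_i, row_j]] = False
                A = b[keep] - b[row_i]
                C = c[keep] - c[row_i]
                lo, hi = -reach, reach
                pos, neg, zero = A > 0, A < 0, A == 0
                if np.any(zero & (C < 0)):
                    continue
                if pos.any():
                    lo = max(lo, float((-C[pos] / A[pos]).max()))
                if neg.any():
                    hi = min(hi, float((-C[neg] / A[neg]).min()))
                if hi - lo > min_edge:
                    adjacent = True
                    break
            if adjacent:
                adjacency[i].add(j)
                adjacency[j].add(i)
    return adjacency


def circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, np.hypot(*(np.asarray(a) - center))


class TestReplicate:
    def test_full_replication_count(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (16, 2))
        ext, image_of = replicate_periodic(pts, (10.0, 10.0), margin=10.0)
        assert len(ext) == 9 * 16
        assert (image_of[:16] == np.arange(16)).all()

    def test_margin_geometry(self):
        pts = np.array([[0.1, 0.1]])
        ext, _ = replicate_periodic(pts, (10.0, 10.0), margin=1.0)
        rows = {tuple(np.round(p, 6)) for p in ext}
        assert (10.1, 0.1) in rows
        assert (0.1, 10.1) in rows
        assert (10.1, 10.1) in rows
        assert not any(x < -1.0 for x, _ in rows)

    def test_primary_points_retained(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 5, (7, 2))
        ext, _ = replicate_periodic(pts, (5.0, 5.0), margin=0.5)
        assert np.array_equal(ext[:7], pts)

    def test_invalid_inputs(self):
        with pytest.raises(TessellationError):
            replicate_periodic(np.zeros((3, 2)), (0.0, 5.0), margin=1.0)
        with pytest.raises(TessellationError):
            replicate_periodic(np.zeros((3, 2)), (5.0, 5.0), margin=0.0)


class TestLattice:
    @pytest.mark.parametrize("k", [3, 4, 8])
    def test_unit_cells_and_four_neighbors(self, k):
        gens = make_generators(lattice_points(k))
        tess = tessellate_leaflet(gens, (float(k), float(k)))
        assert tess.areas == pytest.approx(np.ones(k * k), abs=1e-10)
        assert all(len(nb) == 4 for nb in tess.adjacency)

    def test_scaled_lattice(self):
        gens = make_generators(lattice_points(8, spacing=0.8))
        tess = tessellate_leaflet(gens, (6.4, 6.4))
        assert tess.areas == pytest.approx(np.full(64, 0.64), abs=1e-10)


class TestAreaConservation:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_configurations_tile_the_box(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 257))
        lx, ly = rng.uniform(4.0, 20.0, 2)
        gens = make_generators(np.column_stack(
            [rng.uniform(0, lx, n), rng.uniform(0, ly, n)]
        ))
        tess = tessellate_leaflet(gens, (lx, ly))
        assert abs(tess.areas.sum() - lx * ly) <= 1e-8 * lx * ly
        assert (tess.areas > 0).all()

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 12.0, (40, 2))
        box = (12.0, 12.0)
        t1 = tessellate_leaflet(make_generators(pts), box)
        shift = np.array([3.7, -5.1])
        t2 = tessellate_leaflet(make_generators(pts + shift), box)
        assert np.abs(t1.areas - t2.areas).max() <= 1e-8 * max(t1.areas.max(), 1.0)

    def test_doubled_box_tiling(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 6.0, (20, 2))
        box = (6.0, 6.0)
        t1 = tessellate_leaflet(make_generators(pts), box)
        tiled = np.concatenate([
            pts + np.array([sx * 6.0, sy * 6.0])
            for sx in (0, 1) for sy in (0, 1)
        ])
        t2 = tessellate_leaflet(make_generators(tiled), (12.0, 12.0))
        # each original cell area appears four times
        for i in range(20):
            copies = t2.areas[[i, i + 20, i + 40, i + 60]]
            assert copies == pytest.approx(np.full(4, t1.areas[i]), rel=1e-8)


class TestOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_adjacency_matches_bisector_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 33))
        lx, ly = rng.uniform(4.0, 8.0, 2)
        pts = np.column_stack([rng.uniform(0, lx, n), rng.uniform(0, ly, n)])
        tess = tessellate_leaflet(make_generators(pts), (lx, ly))
        oracle = bruteforce_adjacency(pts, (lx, ly))
        assert tess.adjacency == oracle

    @pytest.mark.parametrize("seed", range(4))
    def test_empty_circumcircle_property(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(6, 21))
        lx, ly = rng.uniform(4.0, 7.0, 2)
        pts = np.column_stack([rng.uniform(0, lx, n), rng.uniform(0, ly, n)])
        tess = tessellate_leaflet(make_generators(pts), (lx, ly))
        ext = tess.ext_points
        n_primary = n
        for simplex in tess.delaunay.simplices:
            if np.all(simplex >= n_primary):
                continue
            center, radius = circumcircle(*(ext[v] for v in simplex))
            dist = np.hypot(*(ext - center).T)
            inside = dist < radius - 1e-9
            inside[simplex] = False
            assert not inside.any()


class TestDegenerate:
    def test_too_few_generators(self):
        with pytest.raises(TessellationError, match="at least 3"):
            tessellate_leaflet(make_generators([(0, 0), (1, 1)]), (4.0, 4.0))

    def test_duplicate_positions_perturbed(self):
        pts = [(1.0, 1.0), (1.0, 1.0), (3.0, 3.0), (1.0, 3.0)]
        tess = tessellate_leaflet(make_generators(pts), (4.0, 4.0))
        assert abs(tess.areas.sum() - 16.0) <= 1e-8 * 16.0
        # the duplicate pair splits one cell roughly in half
        assert tess.areas[0] > 0 and tess.areas[1] > 0

    def test_adjacency_symmetric(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 9.0, (30, 2))
        tess = tessellate_leaflet(make_generators(pts), (9.0, 9.0))
        for i, nbs in enumerate(tess.adjacency):
            assert len(nbs) >= 3
            for j in nbs:
                assert i in tess.adjacency[j]


class TestInclusions:
    def test_no_non_lipid_residues(self, flat_lattice_system):
        from voromem.leaflets import assign_by_position

        system = flat_lattice_system
        topo = system_topology(system)
        frame = system.frames[0]
        assignment = assign_by_position(frame, topo, degree=0)
        gens = insert_inclusions(frame, topo, assignment, "upper")
        assert all(g.kind == LIPID for g in gens)
        assert len(gens) == 16

    def test_inclusion_atoms_join_each_leaflet(self):
        from voromem.leaflets import assign_by_position
        from voromem.synth import InclusionSpec, SynthSpec, build_system

        system = build_system(
            SynthSpec(nx=8, ny=8, spacing=1.0,
                      inclusion=InclusionSpec(radius=1.5, n_atoms=12))
        )
        topo = system_topology(system)
        frame = system.frames[0]
        assignment = assign_by_position(frame, topo, degree=0)
        for leaflet in ("upper", "lower"):
            gens = insert_inclusions(frame, topo, assignment, leaflet,
                                     slab_margin=0.5)
            n_incl = sum(g.kind == INCLUSION for g in gens)
            assert n_incl == 12  # one ring of the cylinder per leaflet slab
            tess = tessellate_leaflet(gens, (8.0, 8.0))
            lipid_area = sum(
                tess.areas[g.id] for g in gens if g.kind == LIPID
            )
            assert lipid_area < 64.0
            assert abs(tess.areas.sum() - 64.0) <= 1e-8 * 64.0
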