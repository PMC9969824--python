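"""Leaflet assignment for planar lipid bilayers.

Two methods are provided:

* **orientation** — the head-minus-tail vector of each lipid: a head above
  the mean tail position (positive z component) puts the lipid in the upper
  leaflet.  Fast, but fooled by lipids whose conformation inverts the
  head-tail order (complex lipids, lipids packed against a protein).
* **position** — fit a polynomial midsurface z = f(x, y) to all key atoms
  by least squares and classify each lipid by the sign of its key atom's
  residual.  Robust to inverted conformations as long as the membrane is a
  single (possibly gently curved) sheet spanning the xy plane.

The membrane normal is assumed parallel to z and the membrane is assumed
not to be split across the z periodic boundary.  Monomials are evaluated on
raw (unwrapped) coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajio import FrameData, Topology

logger = logging.getLogger(__name__)

UPPER = "upper"
LOWER = "lower"

DEFAULT_DEGREE = 2


class LeafletError(Exception):
    pass


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (a, b) with a + b <= degree, in a fixed order."""
    if degree < 0:
        raise LeafletError("polynomial degree must be >= 0")
    return [(a, t - a) for t in range(degree + 1) for a in range(t, -1, -1)]


@dataclass(frozen=True)
class PolynomialSurface:
    """Bivariate polynomial z = f(x, y) of total degree ``degree``.

    ``coeffs[k]`` multiplies ``x**a * y**b`` for the k-th pair returned by
    :func:`monomial_exponents`; the count is ``(d+1)(d+2)/2``.
    """

    degree: int
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        expected = (self.degree + 1) * (self.degree + 2) // 2
        if len(self.coeffs) != expected:
            raise LeafletError(
                f"degree {self.degree} needs {expected} coefficients, "
                f"got {len(self.coeffs)}"
            )

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        for c, (a, b) in zip(self.coeffs, monomial_exponents(self.degree)):
            z += c * x**a * y**b
        return z


def design_matrix(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    exps = monomial_exponents(degree)
    return np.column_stack([x**a * y**b for a, b in exps])


def fit_midplane(points: np.ndarray, degree: int) -> PolynomialSurface:
    """Least-squares fit of z on monomials x^a y^b with a + b <= degree.

    ``points`` is an (n, 3) array in nm.  Raises :class:`LeafletError` if
    the system is underdetermined (fewer points than monomials) or the
    design matrix is rank-deficient (e.g. all points collinear in xy).
    """
    points = np.asarray(points, dtype=float)
    n_coef = (degree + 1) * (degree + 2) // 2
    if len(points) < n_coef:
        raise LeafletError(
            f"degree {degree} fit needs at least {n_coef} points, got {len(points)}"
        )
    A = design_matrix(points[:, 0], points[:, 1], degree)
    coeffs, _, rank, _ = np.linalg.lstsq(A, points[:, 2], rcond=None)
    if rank < n_coef:
        raise LeafletError(
            f"rank-deficient design (rank {rank} < {n_coef}): "
            "points may be collinear in the xy plane"
        )
    return PolynomialSurface(degree=degree, coeffs=coeffs)


@dataclass
class LeafletAssignment:
    """Per-lipid upper/lower labels with the method that produced them."""

    labels: np.ndarray  # array of "upper"/"lower", one per lipid
    method: str  # "orientation" | "position"
    degree: int | None = None
    surface: PolynomialSurface | None = None

    def lipid_ids(self, leaflet: str) -> np.ndarray:
        return np.nonzero(self.labels == leaflet)[0]

    @property
    def n_upper(self) -> int:
        return int(np.sum(self.labels == UPPER))

    @property
    def n_lower(self) -> int:
        return int(np.sum(self.labels == LOWER))


def _orientation_z(frame: FrameData, topology: Topology) -> np.ndarray:
    """z component of head - mean(tails) for every lipid."""
    dz = np.empty(topology.n_lipids)
    for lp in topology.lipids:
        if not lp.tail_indices:
            raise LeafletError(
                f"lipid {lp.resname} {lp.residue_id} has no tail atoms; "
                "orientation-based detection needs at least one"
            )
        head_z = frame.positions[lp.head_index, 2]
        tail_z = frame.positions[list(lp.tail_indices), 2].mean()
        dz[lp.lipid_id] = head_z - tail_z
    return dz


def assign_by_orientation(frame: FrameData, topology: Topology) -> LeafletAssignment:
    """Label lipids by the sign of the head-minus-tail z component.

    A z component of exactly zero is broken towards the upper leaflet with
    a warning.
    """
    dz = _orientation_z(frame, topology)
    n_zero = int(np.sum(dz == 0.0))
    if n_zero:
        logger.warning(
            "%d lipid(s) with exactly horizontal orientation assigned to upper leaflet",
            n_zero,
        )
    labels = np.where(dz >= 0.0, UPPER, LOWER)
    return LeafletAssignment(labels=labels, method="orientation")


def assign_by_position(
    frame: FrameData,
    topology: Topology,
    degree: int = DEFAULT_DEGREE,
    all_atoms: bool = False,
) -> LeafletAssignment:
    """Label lipids by their key atom's side of a fitted midsurface.

    A polynomial surface of the given degree is fitted to all lipid key
    atoms (or, with ``all_atoms=True``, to every lipid atom).  Lipids with
    a residual of exactly zero fall back to the orientation rule, with a
    warning.
    """
    heads = topology.head_indices
    if len(heads) == 0:
        raise LeafletError("topology contains no lipids")
    fit_points = (
        frame.positions[topology.lipid_atom_indices()]
        if all_atoms
        else frame.positions[heads]
    )
    surface = fit_midplane(fit_points, degree)
    head_pos = frame.positions[heads]
    residual = head_pos[:, 2] - surface.evaluate(head_pos[:, 0], head_pos[:, 1])
    labels = np.where(residual > 0.0, UPPER, LOWER)
    on_surface = residual == 0.0
    if np.any(on_surface):
        logger.warning(
            "%d lipid(s) exactly on the midsurface; using orientation fallback",
            int(np.sum(on_surface)),
        )
        fallback = assign_by_orientation(frame, topology)
        labels[on_surface] = fallback.labels[on_surface]
    return LeafletAssignment(
        labels=labels, method="position", degree=degree, surface=surface
    )


def assign_leaflets(
    frame: FrameData,
    topology: Topology,
    method: str = "position",
    degree: int = DEFAULT_DEGREE,
) -> LeafletAssignment:
    """Dispatch to the requested leaflet-detection method."""
    if method == "orientation":
        return assign_by_orientation(frame, topology)
    if method == "position":
        return assign_by_position(frame, topology, degree=degree)
    raise LeafletError(f"unknown leaflet method {method!r}")
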