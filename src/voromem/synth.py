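"""Synthetic bilayer generator with recorded ground truth.

Builds flat or gently curved point-lipid bilayers: two leaflets of 3-atom
lipids (head ``P`` plus two tail atoms ``T1``/``T2`` placed 0.5 and 1.0 nm
towards the midplane) on a jittered square lattice, with optional inverted
lipids (tails pointing outwards — head position correct, orientation vector
wrong), an optional cylindrical non-lipid inclusion spanning the bilayer,
and per-frame regenerated Gaussian jitter.  Systems are written as PDB +
XTC (+ NDX group "heads" and a truth TSV) so the whole I/O and analysis
stack can be exercised without external data.

All randomness comes from ``numpy.random.default_rng(seed)`` (PCG64); the
same spec yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajio import FrameData, LipidDefinition, Topology, read_topology, write_index

LIPID_RESNAME = "DPPC"
INCLUSION_RESNAME = "PROT"
HEAD_NAME = "P"
TAIL_NAMES = ("T1", "T2")
TAIL_OFFSETS = (0.5, 1.0)  # nm towards the midplane


class SynthError(Exception):
    pass


@dataclass(frozen=True)
class InclusionSpec:
    """Cylindrical non-lipid inclusion centered in the box.

    ``n_atoms`` atoms are placed on a ring of radius ``ring_fraction *
    radius`` at each of three z levels (lower leaflet, midplane, upper
    leaflet); lattice sites within ``radius`` of the axis carry no lipid.
    """

    radius: float  # nm
    n_atoms: int = 12  # atoms per ring
    ring_fraction: float = 0.7


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic bilayer.

    Defaults emulate a small fluid-phase phosphatidylcholine patch: lattice
    spacing 0.8 nm (area per lipid 0.64 nm^2), phosphate-to-phosphate
    thickness 4.0 nm, mild positional jitter.
    """

    nx: int = 8
    ny: int = 8
    spacing: float = 0.8  # nm
    thickness: float = 4.0  # nm (head-plane separation)
    jitter_xy: float = 0.0  # Gaussian sigma, nm
    jitter_z: float = 0.0
    curvature_amplitude: float = 0.0  # nm; 0 = flat, else quadratic bulge in x
    inverted_fraction: float = 0.0
    inclusion: InclusionSpec | None = None
    n_frames: int = 1
    dt: float = 1.0  # ps between frames
    seed: int = 0

    @property
    def box(self) -> tuple[float, float, float]:
        return (self.nx * self.spacing, self.ny * self.spacing, 2.0 * self.thickness)


def lipid_definition() -> LipidDefinition:
    """The lipid definition matching generated bilayers."""
    return LipidDefinition(LIPID_RESNAME, HEAD_NAME, TAIL_NAMES)


@dataclass
class SynthSystem:
    """In-memory synthetic system: atoms, frames and ground truth."""

    spec: SynthSpec
    atom_names: list[str]
    resnames: list[str]
    resids: list[int]
    frames: list[FrameData]
    truth: pd.DataFrame  # lipid_id, resid, leaflet, inverted
    head_atom_indices: list[int] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_lipids(self) -> int:
        return len(self.truth)


def _midsurface(x: np.ndarray, lx: float, amplitude: float) -> np.ndarray:
    """Quadratic bulge: 0 at the x edges, ``amplitude`` at the center."""
    u = x / lx
    return amplitude * 4.0 * u * (1.0 - u)


def build_system(spec: SynthSpec) -> SynthSystem:
    """Construct the synthetic bilayer in memory (no files written)."""
    if spec.nx * spec.ny < 4:
        raise SynthError("need at least 4 lipids per leaflet (nx*ny >= 4)")
    lx, ly, lz = spec.box
    if spec.inclusion is not None and 2.0 * spec.inclusion.radius >= min(lx, ly):
        raise SynthError(
            f"inclusion radius {spec.inclusion.radius} nm too large for "
            f"{lx:.3g} x {ly:.3g} nm box"
        )
    rng = np.random.default_rng(spec.seed)

    # lattice sites, minus those carved out by the inclusion
    xs = (np.arange(spec.nx) + 0.5) * spec.spacing
    ys = (np.arange(spec.ny) + 0.5) * spec.spacing
    sites = np.array([(x, y) for x in xs for y in ys])
    if spec.inclusion is not None:
        center = np.array([lx / 2.0, ly / 2.0])
        keep = np.hypot(*(sites - center).T) >= spec.inclusion.radius
        sites = sites[keep]
        if len(sites) < 3:
            raise SynthError("inclusion leaves fewer than 3 lipids per leaflet")
    n_per_leaflet = len(sites)

    # deterministic seeded choice of inverted lipids, per leaflet
    n_inv = int(round(spec.inverted_fraction * n_per_leaflet))
    inverted_sets = [
        set(rng.permutation(n_per_leaflet)[:n_inv].tolist()) for _ in range(2)
    ]

    atom_names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    head_atom_indices: list[int] = []
    truth_rows: list[dict] = []
    resid = 0
    for leaflet_i, leaflet in enumerate(("upper", "lower")):
        sign = 1.0 if leaflet == "upper" else -1.0
        for site_i in range(n_per_leaflet):
            resid += 1
            lipid_id = len(truth_rows)
            inverted = site_i in inverted_sets[leaflet_i]
            head_atom_indices.append(len(atom_names))
            for name in (HEAD_NAME, *TAIL_NAMES):
                atom_names.append(name)
                resnames.append(LIPID_RESNAME)
                resids.append(resid)
            truth_rows.append(
                {
                    "lipid_id": lipid_id,
                    "resid": resid,
                    "resname": LIPID_RESNAME,
                    "leaflet": leaflet,
                    "inverted": inverted,
                }
            )
    n_lipids = len(truth_rows)
    if spec.inclusion is not None:
        resid += 1
        for z_level in range(3):
            for k in range(spec.inclusion.n_atoms):
                atom_names.append("CA")
                resnames.append(INCLUSION_RESNAME)
                resids.append(resid)

    truth = pd.DataFrame(truth_rows).set_index("lipid_id")

    z_center = lz / 2.0  # membrane midplane sits at the box center
    frames: list[FrameData] = []
    for f in range(spec.n_frames):
        pos = np.empty((len(atom_names), 3))
        a = 0
        li = 0
        for leaflet_i, leaflet in enumerate(("upper", "lower")):
            sign = 1.0 if leaflet == "upper" else -1.0
            for site_i in range(n_per_leaflet):
                x0, y0 = sites[site_i]
                jx = rng.normal(0.0, spec.jitter_xy) if spec.jitter_xy > 0 else 0.0
                jy = rng.normal(0.0, spec.jitter_xy) if spec.jitter_xy > 0 else 0.0
                jz = rng.normal(0.0, spec.jitter_z) if spec.jitter_z > 0 else 0.0
                x = (x0 + jx) % lx
                y = (y0 + jy) % ly
                z_mid = z_center + _midsurface(x0, lx, spec.curvature_amplitude)
                head_z = z_mid + sign * spec.thickness / 2.0 + jz
                inverted = site_i in inverted_sets[leaflet_i]
                # tails point towards the midplane; inverted lipids have the
                # head/tail z-order swapped (tails outwards, head in place)
                tail_dir = sign if inverted else -sign
                pos[a] = (x, y, head_z)
                for t, off in enumerate(TAIL_OFFSETS):
                    pos[a + 1 + t] = (x, y, head_z + tail_dir * off)
                a += 3
                li += 1
        if spec.inclusion is not None:
            r_ring = spec.inclusion.ring_fraction * spec.inclusion.radius
            for z_level, zl in enumerate(
                (z_center - spec.thickness / 2.0, z_center,
                 z_center + spec.thickness / 2.0)
            ):
                for k in range(spec.inclusion.n_atoms):
                    ang = 2.0 * math.pi * k / spec.inclusion.n_atoms
                    pos[a] = (
                        lx / 2.0 + r_ring * math.cos(ang),
                        ly / 2.0 + r_ring * math.sin(ang),
                        zl,
                    )
                    a += 1
        frames.append(
            FrameData(positions=pos, box=(lx, ly, lz), time=f * spec.dt, frame_index=f)
        )

    return SynthSystem(
        spec=spec,
        atom_names=atom_names,
        resnames=resnames,
        resids=resids,
        frames=frames,
        truth=truth,
        head_atom_indices=head_atom_indices,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _write_pdb(system: SynthSystem, path: Path) -> None:
    lx, ly, lz = system.frames[0].box
    pos = system.frames[0].positions
    with open(path, "w") as fh:
        fh.write(
            f"CRYST1{lx * 10:9.3f}{ly * 10:9.3f}{lz * 10:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for i, (name, resname, resid) in enumerate(
            zip(system.atom_names, system.resnames, system.resids)
        ):
            x, y, z = pos[i] * 10.0  # nm -> Angstrom
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                f"ATOM  {i + 1:5d} {pdb_name}{'':1s}{resname:<4s}A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{name[0]:>2s}\n"
            )
        fh.write("END\n")


XTC_PRECISION = 1000.0  # coordinates stored as nm * 1000 rounded to integers


def _write_xdr(system: SynthSystem, path: Path, fmt: str) -> None:
    # low-level XDR codecs take nm directly: frames are stored without any
    # unit conversion, so TRR round trips are bit-faithful at float32
    from MDAnalysis.lib.formats.libmdaxdr import TRRFile, XTCFile

    file_cls = {"xtc": XTCFile, "trr": TRRFile}[fmt]
    with file_cls(str(path), "w") as xdr:
        for frame in system.frames:
            xyz = np.ascontiguousarray(frame.positions, dtype=np.float32)
            box = np.diag(np.asarray(frame.box, dtype=np.float32))
            if fmt == "xtc":
                xdr.write(xyz, box, frame.frame_index, frame.time, XTC_PRECISION)
            else:
                xdr.write(
                    xyz, None, None, box, frame.frame_index, frame.time, 0.0,
                    len(xyz),
                )


def write_frames(
    frames: list[FrameData], path: str | Path, trajectory_format: str = "xtc"
) -> None:
    """Write bare frames to XTC/TRR (test-fixture utility)."""
    if not frames:
        raise SynthError("no frames to write")
    shell = SynthSystem(
        spec=SynthSpec(),
        atom_names=["X"] * len(frames[0].positions),
        resnames=["UNK"] * len(frames[0].positions),
        resids=[1] * len(frames[0].positions),
        frames=frames,
        truth=pd.DataFrame(),
    )
    _write_xdr(shell, Path(path), trajectory_format)


def write_system(
    system: SynthSystem, out_prefix: str | Path, trajectory_format: str = "xtc"
) -> dict[str, Path]:
    """Write PDB, trajectory, NDX ("heads" group) and truth TSV files.

    Returns a mapping of output kind to path.  Output is deterministic:
    the same system writes byte-identical files.
    """
    if trajectory_format not in ("xtc", "trr"):
        raise SynthError(f"unsupported trajectory format {trajectory_format!r}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": out_prefix.with_suffix(".pdb"),
        "traj": out_prefix.with_suffix(f".{trajectory_format}"),
        "ndx": out_prefix.with_suffix(".ndx"),
        "truth": Path(str(out_prefix) + "_truth.tsv"),
    }
    _write_pdb(system, paths["pdb"])
    _write_xdr(system, paths["traj"], trajectory_format)
    write_index({"heads": system.head_atom_indices}, paths["ndx"])
    system.truth.to_csv(paths["truth"], sep="\t")
    return paths


def generate_bilayer(
    spec: SynthSpec, out_prefix: str | Path, trajectory_format: str = "xtc"
) -> tuple[SynthSystem, dict[str, Path]]:
    """Build a synthetic bilayer and write all its files."""
    system = build_system(spec)
    return system, write_system(system, out_prefix, trajectory_format)


def load_topology(paths: dict[str, Path]) -> Topology:
    """Convenience: read back a generated system's topology."""
    return read_topology(paths["pdb"], [lipid_definition()])
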