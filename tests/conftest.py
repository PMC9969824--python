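import numpy as np
import pytest

from voromem.synth import SynthSpec, build_system, generate_bilayer, lipid_definition
from voromem.tessellate import LIPID, Generator
from voromem.trajio import FrameData, LipidRecord, Topology, read_topology


def make_generators(points, box=None, z=0.0):
    """Lipid generators at explicit xy points (lipid_id = order)."""
    return [
        Generator(id=i, kind=LIPID, xy=(float(x), float(y)), z=z, lipid_id=i)
        for i, (x, y) in enumerate(points)
    ]


def lattice_points(k, spacing=1.0):
    """k x k square lattice with sites at cell centers."""
    c = (np.arange(k) + 0.5) * spacing
    return np.array([(x, y) for x in c for y in c])


def system_topology(system):
    """Topology built straight from an in-memory synthetic system."""
    topo = Topology(
        atom_names=np.array(system.atom_names),
        resnames=np.array(system.resnames),
        resids=np.array(system.resids),
    )
    topo.lipids = [
        LipidRecord(
            i,
            int(row["resid"]),
            row["resname"],
            system.head_atom_indices[i],
            (system.head_atom_indices[i] + 1, system.head_atom_indices[i] + 2),
        )
        for i, (_, row) in enumerate(system.truth.iterrows())
    ]
    return topo


def make_point_topology(resnames):
    """Minimal topology with one atom per lipid (head = the atom itself)."""
    n = len(resnames)
    topo = Topology(
        atom_names=np.array(["P"] * n),
        resnames=np.array(resnames),
        resids=np.arange(1, n + 1),
    )
    topo.lipids = [
        LipidRecord(i, i + 1, resnames[i], i, ()) for i in range(n)
    ]
    return topo


def make_point_frame(xy, z, box):
    """Frame for a point topology: one 3D position per lipid."""
    pos = np.column_stack([np.asarray(xy), np.asarray(z, dtype=float)])
    return FrameData(positions=pos, box=box)


@pytest.fixture(scope="session")
def flat_lattice_system():
    """Zero-jitter 4x4-per-leaflet flat bilayer (32 lipids, 96 atoms)."""
    return build_system(SynthSpec(nx=4, ny=4, spacing=1.0, thickness=4.0))


@pytest.fixture(scope="session")
def flat_lattice_files(tmp_path_factory):
    """The same flat bilayer written to disk, plus its re-read topology."""
    out = tmp_path_factory.mktemp("flat") / "bilayer"
    system, paths = generate_bilayer(
        SynthSpec(nx=4, ny=4, spacing=1.0, thickness=4.0, n_frames=3), out
    )
    topology = read_topology(paths["pdb"], [lipid_definition()])
    return system, paths, topology
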