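"""Input/output for bilayer trajectory analysis.

Reads PDB topologies, GROMACS NDX index groups and XTC/TRR trajectories;
writes XVG (Grace dialect) time series and per-frame TXT/XML exports.

Internal length unit is nanometres everywhere.  PDB/MDAnalysis coordinates
(Angstrom) are divided by 10 at this boundary.  Atom and lipid indices are
0-based internally; NDX files and human-readable exports use 1-based ids.
Only orthorhombic boxes are supported: a triclinic box raises
:class:`UnsupportedBoxError`.
"""

from __future__ import annotations

import logging
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import FrameMetrics, TimeSeries

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0
_BOX_ANGLE_TOL = 1e-3  # degrees


class TrajioError(Exception):
    """Base error for topology / trajectory / export problems."""


class TopologyError(TrajioError):
    pass


class TrajectoryError(TrajioError):
    pass


class IndexFileError(TrajioError):
    pass


class ExportError(TrajioError):
    pass


class UnsupportedBoxError(TrajioError):
    """Raised for triclinic (non-orthorhombic) simulation boxes."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidDefinition:
    """Which atoms represent a lipid species.

    ``head_atom`` is the key atom whose position generates the tessellation
    cell (typically the phosphate phosphorus).  ``tail_atoms`` are candidate
    names for the terminal acyl atoms used by orientation-based leaflet
    detection; only the names actually present in a residue are used.
    """

    resname: str
    head_atom: str
    tail_atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.head_atom in self.tail_atoms:
            raise ValueError(
                f"head atom {self.head_atom!r} of {self.resname} also listed as tail"
            )
        if not self.tail_atoms:
            raise ValueError(f"{self.resname}: tail_atoms must be non-empty")


#: Default key-atom definitions for common phospholipids.  The phosphate
#: phosphorus "P" is the conventional key atom; tail candidates cover the
#: terminal acyl carbons of common two-tail lipids plus the generic "T1"/"T2"
#: names used by the synthetic bilayer generator.
_COMMON_TAILS = ("T1", "T2", "C216", "C316", "C214", "C314", "C218", "C318")
DEFAULT_LIPID_DEFS: tuple[LipidDefinition, ...] = tuple(
    LipidDefinition(resname, "P", _COMMON_TAILS)
    for resname in ("DPPC", "DMPC", "DSPC", "DOPC", "POPC", "POPE", "DPPE", "DOPE")
)


@dataclass(frozen=True)
class LipidRecord:
    """One resolved lipid: residue identity plus head/tail atom indices."""

    lipid_id: int
    residue_id: int
    resname: str
    head_index: int
    tail_indices: tuple[int, ...]


@dataclass
class Topology:
    """Structure-only description of the system (no coordinates).

    ``atom_names`` / ``resnames`` / ``resids`` are parallel arrays over all
    atoms, indices contiguous from 0.  ``lipids`` holds one record per
    residue matched by a :class:`LipidDefinition`.
    """

    atom_names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    lipids: list[LipidRecord] = field(default_factory=list)
    lipid_defs: tuple[LipidDefinition, ...] = DEFAULT_LIPID_DEFS

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    @property
    def head_indices(self) -> np.ndarray:
        return np.array([lp.head_index for lp in self.lipids], dtype=int)

    @property
    def lipid_resnames(self) -> np.ndarray:
        return np.array([lp.resname for lp in self.lipids])

    def lipid_atom_indices(self) -> np.ndarray:
        """Indices of every atom belonging to a lipid residue."""
        lipid_resids = {lp.residue_id for lp in self.lipids}
        mask = np.array([rid in lipid_resids for rid in self.resids])
        return np.nonzero(mask)[0]

    def non_lipid_atom_indices(self) -> np.ndarray:
        lipid_resids = {lp.residue_id for lp in self.lipids}
        mask = np.array([rid not in lipid_resids for rid in self.resids])
        return np.nonzero(mask)[0]


@dataclass
class FrameData:
    """Coordinates (nm) and orthorhombic box of one trajectory frame."""

    positions: np.ndarray  # (n_atoms, 3) nm
    box: tuple[float, float, float]  # (lx, ly, lz) nm
    time: float = 0.0  # ps
    frame_index: int = 0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.box):
            raise TrajectoryError(f"box lengths must be positive, got {self.box}")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("non-finite coordinates in frame")


@dataclass(frozen=True)
class FrameRange:
    """Inclusive frame slice [first, last] with a stride.

    ``last=None`` means end-of-file.  With ``last`` explicit the number of
    yielded frames is ``(last - first) // stride + 1``.
    """

    first: int = 0
    last: int | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        if self.first < 0:
            raise ValueError("first must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.last is not None and self.last < self.first:
            raise ValueError("last must be >= first")

    def indices(self, n_frames: int) -> range:
        """Frame indices selected from a file with ``n_frames`` frames."""
        last = n_frames - 1 if self.last is None else self.last
        if last >= n_frames:
            raise TrajectoryError(
                f"frame range last={last} beyond trajectory end ({n_frames} frames)"
            )
        if self.first >= n_frames:
            raise TrajectoryError(
                f"frame range first={self.first} beyond trajectory end"
            )
        return range(self.first, last + 1, self.stride)

    def count(self, n_frames: int) -> int:
        return len(self.indices(n_frames))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _check_orthorhombic(dimensions: Sequence[float]) -> tuple[float, float, float]:
    lx, ly, lz, alpha, beta, gamma = dimensions
    if any(abs(a - 90.0) > _BOX_ANGLE_TOL for a in (alpha, beta, gamma)):
        raise UnsupportedBoxError(
            f"triclinic box (angles {alpha:.2f}/{beta:.2f}/{gamma:.2f}) is not supported"
        )
    return (lx / ANGSTROM_PER_NM, ly / ANGSTROM_PER_NM, lz / ANGSTROM_PER_NM)


def read_topology(
    pdb_path: str | Path,
    lipid_defs: Iterable[LipidDefinition] = DEFAULT_LIPID_DEFS,
) -> Topology:
    """Parse a PDB file into a :class:`Topology`.

    Coordinates in the PDB are structure metadata only and are discarded
    here; use :func:`read_reference_frame` to retrieve them as a frame.
    Each residue whose resname matches a definition must contain exactly
    one atom named ``head_atom``, otherwise :class:`TopologyError` is
    raised naming the residue.
    """
    import MDAnalysis as mda

    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise TopologyError(f"topology file not found: {pdb_path}")
    defs = tuple(lipid_defs)
    by_resname = {d.resname: d for d in defs}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(pdb_path), format="PDB")
        except Exception as exc:  # qualify parser failures
            raise TopologyError(f"cannot parse PDB {pdb_path}: {exc}") from exc

    topo = Topology(
        atom_names=u.atoms.names.astype(str),
        resnames=u.atoms.resnames.astype(str),
        resids=u.atoms.resids.astype(int),
        lipid_defs=defs,
    )
    lipid_id = 0
    for res in u.residues:
        ldef = by_resname.get(res.resname)
        if ldef is None:
            continue
        names = list(res.atoms.names)
        head_hits = [a.ix for a, nm in zip(res.atoms, names) if nm == ldef.head_atom]
        if len(head_hits) != 1:
            raise TopologyError(
                f"residue {res.resname} {res.resid}: expected exactly one head atom "
                f"{ldef.head_atom!r}, found {len(head_hits)}"
            )
        tails = tuple(
            int(a.ix) for a, nm in zip(res.atoms, names) if nm in ldef.tail_atoms
        )
        topo.lipids.append(
            LipidRecord(lipid_id, int(res.resid), str(res.resname), int(head_hits[0]), tails)
        )
        lipid_id += 1
    if not topo.lipids:
        logger.warning("no residues matched any lipid definition in %s", pdb_path)
    return topo


def read_reference_frame(pdb_path: str | Path) -> FrameData:
    """Return the PDB coordinates as a frame (Angstrom converted to nm)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path), format="PDB")
    if u.dimensions is None:
        raise TrajectoryError(f"{pdb_path}: no CRYST1 box record")
    box = _check_orthorhombic(u.dimensions)
    return FrameData(
        positions=u.atoms.positions.astype(float) / ANGSTROM_PER_NM,
        box=box,
        time=0.0,
        frame_index=0,
    )


def read_trajectory(
    traj_path: str | Path,
    topology: Topology,
    frame_range: FrameRange = FrameRange(),
) -> Iterator[FrameData]:
    """Stream frames from an XTC or TRR file, one frame in memory at a time.

    Honors ``frame_range`` (inclusive first/last, stride).  Coordinates are
    converted to nm.  Raises :class:`TrajectoryError` on atom-count mismatch
    with ``topology``.
    """
    from MDAnalysis.coordinates.TRR import TRRReader
    from MDAnalysis.coordinates.XTC import XTCReader

    traj_path = Path(traj_path)
    if not traj_path.exists():
        raise TrajectoryError(f"trajectory file not found: {traj_path}")
    suffix = traj_path.suffix.lower()
    if suffix == ".xtc":
        reader_cls = XTCReader
    elif suffix == ".trr":
        reader_cls = TRRReader
    else:
        raise TrajectoryError(f"unsupported trajectory format: {suffix!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # XTC/TRR are natively in nm: skip MDAnalysis' Angstrom conversion
        # so coordinates pass through without unit round-off
        reader = reader_cls(str(traj_path), convert_units=False)
    try:
        if reader.n_atoms != topology.n_atoms:
            raise TrajectoryError(
                f"atom count mismatch: trajectory has {reader.n_atoms}, "
                f"topology has {topology.n_atoms}"
            )
        n_frames = len(reader)
        for i in frame_range.indices(n_frames):
            ts = reader[i]
            lx, ly, lz, alpha, beta, gamma = ts.dimensions
            if any(abs(a - 90.0) > _BOX_ANGLE_TOL for a in (alpha, beta, gamma)):
                raise UnsupportedBoxError(
                    f"triclinic box (angles {alpha:.2f}/{beta:.2f}/{gamma:.2f}) "
                    "is not supported"
                )
            yield FrameData(
                positions=ts.positions.astype(float),
                box=(float(lx), float(ly), float(lz)),
                time=float(ts.time),
                frame_index=i,
            )
    finally:
        reader.close()


def trajectory_length(traj_path: str | Path) -> int:
    """Number of frames in an XTC/TRR file."""
    from MDAnalysis.coordinates.TRR import TRRReader
    from MDAnalysis.coordinates.XTC import XTCReader

    suffix = Path(traj_path).suffix.lower()
    reader_cls = {".xtc": XTCReader, ".trr": TRRReader}.get(suffix)
    if reader_cls is None:
        raise TrajectoryError(f"unsupported trajectory format: {suffix!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(traj_path))
    try:
        return len(reader)
    finally:
        reader.close()


_NDX_GROUP_RE = re.compile(r"^\s*\[\s*(.+?)\s*\]\s*$")


def read_index(ndx_path: str | Path, n_atoms: int | None = None) -> dict[str, list[int]]:
    """Read a GROMACS NDX file into ``{group: [0-based indices]}``.

    Duplicate group names get deterministic ``_2``, ``_3`` ... suffixes.
    Indices outside ``[1, n_atoms]`` (when ``n_atoms`` is given) raise
    :class:`IndexFileError`.
    """
    groups: dict[str, list[int]] = {}
    current: list[int] | None = None
    current_name = ""
    with open(ndx_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";")[0].strip()
            if not line:
                continue
            m = _NDX_GROUP_RE.match(line)
            if m:
                name = m.group(1)
                if name in groups:
                    k = 2
                    while f"{name}_{k}" in groups:
                        k += 1
                    name = f"{name}_{k}"
                current = groups.setdefault(name, [])
                current_name = name
                continue
            if current is None:
                raise IndexFileError(f"{ndx_path}:{lineno}: indices before any [ group ]")
            for tok in line.split():
                try:
                    idx = int(tok)
                except ValueError as exc:
                    raise IndexFileError(
                        f"{ndx_path}:{lineno}: invalid index {tok!r}"
                    ) from exc
                if idx <= 0 or (n_atoms is not None and idx > n_atoms):
                    raise IndexFileError(
                        f"{ndx_path}:{lineno}: index {idx} out of range in group "
                        f"{current_name!r}"
                    )
                current.append(idx - 1)
    for name, members in groups.items():
        if not members:
            logger.warning("NDX group %r is empty", name)
    return groups


def write_index(groups: dict[str, Sequence[int]], ndx_path: str | Path) -> None:
    """Write 0-based index groups as a GROMACS NDX file (1-based on disk)."""
    with open(ndx_path, "w") as fh:
        for name, members in groups.items():
            fh.write(f"[ {name} ]\n")
            line: list[str] = []
            for idx in members:
                line.append(str(idx + 1))
                if len(line) == 15:
                    fh.write(" ".join(line) + "\n")
                    line = []
            if line:
                fh.write(" ".join(line) + "\n")


# ---------------------------------------------------------------------------
# Writers: XVG / TXT / XML exports
# ---------------------------------------------------------------------------


def write_xvg(
    series: "TimeSeries",
    path: str | Path,
    title: str = "",
    xaxis: str = "Time (ps)",
    yaxis: str = "",
) -> None:
    """Write a time series as a Grace-dialect XVG file.

    Layout: ``#`` comments, ``@`` directives (title, axis labels, one legend
    per column), then whitespace-separated numeric rows with x first.
    Values are printed with 10 significant digits so re-parsing reproduces
    them well beyond 6 significant digits.  Missing values appear as "nan".
    """
    names = list(series.columns)
    if not names or len(series.x) == 0:
        raise ExportError("cannot write empty series to XVG")
    with open(path, "w") as fh:
        fh.write("# written by voromem\n")
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{xaxis}"\n')
        fh.write(f'@    yaxis  label "{yaxis}"\n')
        fh.write("@TYPE xy\n")
        for k, name in enumerate(names):
            fh.write(f'@ s{k} legend "{name}"\n')
        cols = [np.asarray(series.columns[name], dtype=float) for name in names]
        for i, x in enumerate(np.asarray(series.x, dtype=float)):
            row = [f"{x:.10g}"] + [f"{c[i]:.10g}" for c in cols]
            fh.write(" ".join(row) + "\n")


def read_xvg(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Parse an XVG file back into ``(x, {legend: column})``."""
    legends: list[str] = []
    rows: list[list[float]] = []
    legend_re = re.compile(r'^@ s(\d+) legend "(.*)"')
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                m = legend_re.match(line)
                if m:
                    legends.append(m.group(2))
                continue
            rows.append([float(t) for t in line.split()])
    if not rows:
        raise ExportError(f"no numeric payload in {path}")
    data = np.array(rows, dtype=float)
    x = data[:, 0]
    n_cols = data.shape[1] - 1
    if len(legends) != n_cols:
        legends = [f"s{i}" for i in range(n_cols)]
    return x, {legends[i]: data[:, i + 1] for i in range(n_cols)}


_TXT_COLUMNS = (
    "lipid_id",
    "resname",
    "leaflet",
    "apl_nm2",
    "thickness_nm",
    "n_lipid_neighbors",
    "n_inclusion_neighbors",
    "neighbors",
)


def _neighbor_summary(by_resname: dict[str, int]) -> str:
    if not by_resname:
        return "-"
    return ",".join(f"{k}:{v}" for k, v in sorted(by_resname.items()))


def write_frame_export(metrics: "FrameMetrics", fmt: str, path: str | Path) -> None:
    """Write one frame's per-lipid metrics as TXT or XML.

    TXT: tab-separated, two comment lines (frame header + column header),
    one row per lipid.  Lipid ids are 1-based in both exports.  XML: a
    single ``<frame>`` element with one ``<lipid>`` child per lipid carrying
    the same fields as attributes; floats serialized with ``repr`` so they
    re-parse exactly.  The schema is documented in ``docs/methods.md``.
    """
    if fmt not in ("txt", "xml"):
        raise ExportError(f"unknown export format {fmt!r} (expected 'txt' or 'xml')")
    table = metrics.table
    if fmt == "txt":
        with open(path, "w") as fh:
            fh.write(f"# frame {metrics.frame_index} time {metrics.time:.10g} ps\n")
            fh.write("# " + "\t".join(_TXT_COLUMNS) + "\n")
            for lipid_id, row in table.iterrows():
                fh.write(
                    "\t".join(
                        (
                            str(int(lipid_id) + 1),
                            str(row["resname"]),
                            str(row["leaflet"]),
                            f"{row['apl']:.10g}",
                            f"{row['thickness']:.10g}",
                            str(int(row["n_lipid_neighbors"])),
                            str(int(row["n_inclusion_neighbors"])),
                            _neighbor_summary(row["neighbors"]),
                        )
                    )
                    + "\n"
                )
        return

    root = ET.Element(
        "frame", index=str(metrics.frame_index), time=repr(float(metrics.time))
    )
    for lipid_id, row in table.iterrows():
        ET.SubElement(
            root,
            "lipid",
            id=str(int(lipid_id) + 1),
            resname=str(row["resname"]),
            leaflet=str(row["leaflet"]),
            apl=repr(float(row["apl"])),
            thickness=repr(float(row["thickness"])),
            lipid_neighbors=str(int(row["n_lipid_neighbors"])),
            inclusion_neighbors=str(int(row["n_inclusion_neighbors"])),
            neighbors=_neighbor_summary(row["neighbors"]),
        )
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")


def read_frame_export_xml(path: str | Path) -> dict[int, dict[str, object]]:
    """Parse an XML frame export back into ``{0-based lipid id: fields}``."""
    root = ET.parse(path).getroot()
    out: dict[int, dict[str, object]] = {}
    for el in root.iter("lipid"):
        out[int(el.get("id")) - 1] = {
            "resname": el.get("resname"),
            "leaflet": el.get("leaflet"),
            "apl": float(el.get("apl")),
            "thickness": float(el.get("thickness")),
            "lipid_neighbors": int(el.get("lipid_neighbors")),
            "inclusion_neighbors": int(el.get("inclusion_neighbors")),
        }
    return out


# ---------------------------------------------------------------------------
# Lipid definition config files
# ---------------------------------------------------------------------------


def load_lipid_defs(path: str | Path) -> tuple[LipidDefinition, ...]:
    """Load lipid definitions from a simple key-value config file.

    One lipid per line::

        # resname: head=KEYATOM tails=NAME1,NAME2
        DPPC: head=P tails=C216,C316

    Lines starting with ``#`` are comments.
    """
    defs: list[LipidDefinition] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            m = re.match(
                r"^(\w+)\s*:\s*head\s*=\s*(\S+)\s+tails\s*=\s*(\S+)$", line
            )
            if not m:
                raise TrajioError(f"{path}:{lineno}: cannot parse lipid definition")
            resname, head, tails = m.groups()
            defs.append(LipidDefinition(resname, head, tuple(tails.split(","))))
    if not defs:
        raise TrajioError(f"{path}: no lipid definitions found")
    return tuple(defs)
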