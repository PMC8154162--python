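"""Structure/trajectory I/O and periodic-boundary geometry primitives.

Coordinates are stored in nanometres throughout the package; PDB files
(which print Angstroms) are converted at the read/write boundary.  Only
orthorhombic boxes are supported: the analyses implemented here never need
triclinic cells, and GRO box lines with non-zero off-diagonal components
are rejected with a clear error rather than silently mishandled.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "FormatError",
    "read_structure",
    "write_structure",
    "minimum_image",
    "wrap_positions",
    "make_whole",
    "select",
    "parse_selection",
    "DEFAULT_GROUP_MAP",
]

AMU_TO_G = 1.66053907e-24  # 1 atomic mass unit in grams

GROUP_TAGS = ("host", "guest", "water", "ion", "other")

#: element -> (mass amu, Bondi-style vdW radius nm)
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 0.120),
    "C": (12.011, 0.170),
    "N": (14.007, 0.155),
    "O": (15.999, 0.152),
    "S": (32.06, 0.180),
    "P": (30.974, 0.180),
    "F": (18.998, 0.147),
    "NA": (22.990, 0.227),
    "CL": (35.45, 0.175),
    "K": (39.098, 0.275),
}

DEFAULT_ELEMENT_RADIUS = 0.17  # nm; carbon-dominated systems

# Masses/radii for the coarse bead types emitted by the synthetic generator,
# keyed by (residue prefix, atom name).  A styrene unit (104.15 amu) is two
# beads; a guest molecule (368.38 amu, curcumin-like) is 13 beads; hydration
# waters are single points.
SYNTHETIC_BEADS: dict[tuple[str, str], tuple[float, float]] = {}
for _name in ("CB", "CG"):
    SYNTHETIC_BEADS[("STY", _name)] = (52.075, 0.38)
for _i in range(1, 13):
    SYNTHETIC_BEADS[("CUR", f"C{_i}")] = (368.38 / 13.0, 0.21)
SYNTHETIC_BEADS[("CUR", "CD")] = (368.38 / 13.0, 0.21)
SYNTHETIC_BEADS[("SOL", "MW")] = (18.015, 0.14)

#: residue-name prefix -> group tag (overridable via config)
DEFAULT_GROUP_MAP: dict[str, str] = {
    "STY": "host",
    "PS": "host",
    "CUR": "guest",
    "SOL": "water",
    "HOH": "water",
    "TIP": "water",
    "WAT": "water",
    "NA": "ion",
    "CL": "ion",
    "ION": "ion",
}


class FormatError(ValueError):
    """Raised for malformed or unsupported structure files."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology (identity only; coordinates live in Frame)."""

    index: int  # 1-based serial
    name: str
    element: str
    mass: float  # amu
    vdw_radius: float  # nm
    molecule_id: int
    chain_label: str = ""
    group_tag: str = "other"
    residue_name: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be positive, got {self.mass}")
        if self.vdw_radius < 0:
            raise ValueError(f"atom {self.index}: vdW radius must be >= 0")
        if self.group_tag not in GROUP_TAGS:
            raise ValueError(f"atom {self.index}: unknown group tag {self.group_tag!r}")


@dataclass
class Frame:
    """Coordinates (nm) and orthorhombic box (nm) at one time point (ns)."""

    time: float
    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) edge lengths nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        """Box volume in nm^3."""
        return float(np.prod(self.box))


@dataclass
class Trajectory:
    """Topology plus a time-ordered list of frames."""

    topology: list[AtomRecord]
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.n_atoms != len(self.topology):
                raise ValueError(
                    f"frame at t={f.time} has {f.n_atoms} atoms, topology has {len(self.topology)}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.topology])

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.topology])


# ---------------------------------------------------------------------------
# selections

def select(
    topology: Sequence[AtomRecord] | Trajectory,
    name: str | None = None,
    tag: str | None = None,
    molecule_id: int | None = None,
    residue: str | None = None,
) -> np.ndarray:
    """Indices (0-based) of atoms matching all given criteria."""
    if isinstance(topology, Trajectory):
        topology = topology.topology
    out = []
    for i, a in enumerate(topology):
        if name is not None and a.name != name:
            continue
        if tag is not None and a.group_tag != tag:
            continue
        if molecule_id is not None and a.molecule_id != molecule_id:
            continue
        if residue is not None and not a.residue_name.startswith(residue):
            continue
        out.append(i)
    return np.array(out, dtype=int)


def parse_selection(expr: str) -> dict[str, object]:
    """Parse a tiny selection grammar: clauses joined by "and".

    Supported clauses: ``name <atom name>``, ``tag <group tag>``,
    ``residue <residue prefix>``, ``molecule <id>``.
    """
    kwargs: dict[str, object] = {}
    for clause in expr.split(" and "):
        parts = clause.split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        key, value = parts
        if key == "name":
            kwargs["name"] = value
        elif key == "tag":
            kwargs["tag"] = value
        elif key == "residue":
            kwargs["residue"] = value
        elif key == "molecule":
            kwargs["molecule_id"] = int(value)
        else:
            raise ValueError(f"unknown selection key {key!r}")
    return kwargs


# ---------------------------------------------------------------------------
# periodic-boundary primitives

def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement(s) to the nearest periodic image.

    Each component of the result lies in [-edge/2, edge/2); the returned
    vector has the smallest norm among all periodic images.
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    return d - box * np.floor(d / box + 0.5)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, edge) per axis."""
    return np.mod(positions, np.asarray(box, dtype=float))


def make_whole(frame: Frame, topology: Sequence[AtomRecord]) -> np.ndarray:
    """Return positions with every molecule made whole across the PBC.

    The first atom of each molecule anchors it; every other atom is moved to
    its minimum image relative to that anchor.  Assumes molecular extent is
    below half the box edge (true for all systems handled here).
    """
    pos = frame.positions.copy()
    mol_ids = np.array([a.molecule_id for a in topology])
    for mid in np.unique(mol_ids):
        idx = np.nonzero(mol_ids == mid)[0]
        anchor = pos[idx[0]]
        pos[idx] = anchor + minimum_image(pos[idx] - anchor, frame.box)
    return pos


# ---------------------------------------------------------------------------
# element / mass resolution

def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip().upper()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped in ("NA", "CL", "K") and residue_name.strip().upper().startswith(
        ("NA", "CL", "K", "ION", "SOD", "POT")
    ):
        return stripped
    return stripped[0]


def _resolve_mass_radius(
    atom_name: str, residue_name: str, element: str,
    radius_overrides: dict[str, float] | None,
) -> tuple[float, float]:
    res_prefix = residue_name.strip().upper()[:3]
    key = (res_prefix, atom_name.strip())
    if key in SYNTHETIC_BEADS:
        return SYNTHETIC_BEADS[key]
    if element in ELEMENT_TABLE:
        mass, radius = ELEMENT_TABLE[element]
    else:
        logger.warning(
            "unknown element %r (atom %r): defaulting to mass 12.011 amu, radius %.2f nm",
            element, atom_name, DEFAULT_ELEMENT_RADIUS,
        )
        mass, radius = 12.011, DEFAULT_ELEMENT_RADIUS
    if radius_overrides and element in radius_overrides:
        radius = radius_overrides[element]
    return mass, radius


def _group_tag_for(residue_name: str, group_map: dict[str, str]) -> str:
    res = residue_name.strip().upper()
    for prefix, tag in group_map.items():
        if res.startswith(prefix.upper()):
            return tag
    return "other"


# ---------------------------------------------------------------------------
# GRO

def _parse_gro_box(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: cannot parse box line {line!r}") from exc
    if len(vals) == 3:
        return np.array(vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise FormatError(
                f"line {lineno}: triclinic box (non-zero off-diagonal components) not supported"
            )
        return np.array(vals[:3])
    raise FormatError(f"line {lineno}: box line must have 3 or 9 values, got {len(vals)}")


def _read_gro(lines: list[str], group_map, radius_overrides):
    frames: list[Frame] = []
    topology: list[AtomRecord] | None = None
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = float(frame_index)
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            n_atoms = int(lines[i + 1].strip())
        except (ValueError, IndexError) as exc:
            raise FormatError(f"line {i + 2}: expected atom count, got {lines[i + 1]!r}") from exc
        body = lines[i + 2 : i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise FormatError(
                f"line {i + 2}: header declares {n_atoms} atoms but only {len(body)} lines follow"
            )
        records: list[AtomRecord] = []
        positions = np.empty((n_atoms, 3))
        for j, line in enumerate(body):
            lineno = i + 3 + j
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                serial = int(line[15:20])
                x = float(line[20:28])
                y = float(line[28:36])
                z = float(line[36:44])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {lineno}: malformed GRO atom line {line!r}") from exc
            positions[j] = (x, y, z)
            if topology is None:
                element = _infer_element(name, resname)
                mass, radius = _resolve_mass_radius(name, resname, element, radius_overrides)
                records.append(AtomRecord(
                    index=serial if serial > 0 else j + 1,
                    name=name, element=element, mass=mass, vdw_radius=radius,
                    molecule_id=resid, chain_label="",
                    group_tag=_group_tag_for(resname, group_map),
                    residue_name=resname,
                ))
        box_line_idx = i + 2 + n_atoms
        if box_line_idx >= len(lines):
            raise FormatError(f"line {box_line_idx + 1}: missing box line")
        box = _parse_gro_box(lines[box_line_idx], box_line_idx + 1)
        if topology is None:
            topology = records
        if frames and time <= frames[-1].time:
            time = frames[-1].time + 1.0
        frames.append(Frame(time=time, positions=positions, box=box))
        i = box_line_idx + 1
        frame_index += 1
    if topology is None:
        raise FormatError("empty GRO file")
    return Trajectory(topology=topology, frames=frames)


def _write_gro(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"nanoagg system, t= {frame.time:.4f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for a, p in zip(traj.topology, frame.positions):
                resname = (a.residue_name or "UNK")[:5]
                fh.write(
                    f"{a.molecule_id % 100000:5d}{resname:<5s}{a.name[:5]:>5s}"
                    f"{a.index % 100000:5d}{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n"
                )
            fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB

def _read_pdb(lines: list[str], group_map, radius_overrides):
    frames: list[Frame] = []
    topology: list[AtomRecord] | None = None
    box: np.ndarray | None = None
    cur_pos: list[tuple[float, float, float]] = []
    cur_records: list[AtomRecord] = []
    frame_index = 0
    in_model = False

    def _finish_frame():
        nonlocal topology, frame_index, cur_pos, cur_records
        if not cur_pos:
            return
        if box is None:
            raise FormatError("PDB has coordinates but no CRYST1 box record")
        if topology is None:
            topology = cur_records
        elif len(cur_pos) != len(topology):
            raise FormatError(
                f"MODEL {frame_index + 1} has {len(cur_pos)} atoms, "
                f"first model has {len(topology)}"
            )
        frames.append(Frame(time=float(frame_index), positions=np.array(cur_pos), box=box))
        frame_index += 1
        cur_pos = []
        cur_records = []

    for lineno, raw in enumerate(lines, start=1):
        rec = raw[:6].strip()
        if rec == "CRYST1":
            try:
                a, b, c = float(raw[6:15]), float(raw[15:24]), float(raw[24:33])
                alpha, beta, gamma = float(raw[33:40]), float(raw[40:47]), float(raw[47:54])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {lineno}: malformed CRYST1 record") from exc
            if not (abs(alpha - 90) < 1e-6 and abs(beta - 90) < 1e-6 and abs(gamma - 90) < 1e-6):
                raise FormatError(f"line {lineno}: non-orthorhombic cell not supported")
            box = np.array([a, b, c]) / 10.0  # A -> nm
        elif rec == "MODEL":
            in_model = True
        elif rec == "ENDMDL":
            _finish_frame()
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            try:
                serial = int(raw[6:11])
                name = raw[12:16].strip()
                resname = raw[17:21].strip()
                chain = raw[21:22].strip()
                resseq = int(raw[22:26])
                x = float(raw[30:38]) / 10.0
                y = float(raw[38:46]) / 10.0
                z = float(raw[46:54]) / 10.0
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {lineno}: malformed ATOM/HETATM record {raw!r}") from exc
            element = raw[76:78].strip().upper() if len(raw) >= 78 and raw[76:78].strip() else None
            if not element:
                element = _infer_element(name, resname)
            cur_pos.append((x, y, z))
            if topology is None:
                mass, radius = _resolve_mass_radius(name, resname, element, radius_overrides)
                cur_records.append(AtomRecord(
                    index=serial, name=name, element=element, mass=mass,
                    vdw_radius=radius, molecule_id=resseq, chain_label=chain,
                    group_tag=_group_tag_for(resname, group_map),
                    residue_name=resname,
                ))
    _finish_frame()  # trailing model without ENDMDL, or file without MODEL records
    if topology is None:
        raise FormatError("PDB file contains no ATOM/HETATM records")
    return Trajectory(topology=topology, frames=frames)


def _write_pdb(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        box_a = traj.frames[0].box * 10.0
        fh.write(
            f"CRYST1{box_a[0]:9.3f}{box_a[1]:9.3f}{box_a[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for a, p in zip(traj.topology, frame.positions):
                xa, ya, za = p * 10.0
                name = a.name[:4]
                # PDB convention: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"HETATM{a.index % 100000:5d} {name_field}"
                    f" {(a.residue_name or 'UNK')[:4]:<4s}{(a.chain_label or 'A')[:1]}"
                    f"{a.molecule_id % 10000:4d}    "
                    f"{xa:8.3f}{ya:8.3f}{za:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element[:2]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# public API

def _guess_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("gro", "pdb"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("gro", "pdb"):
        return ext
    raise ValueError(f"cannot infer format from {path!r}; pass format='gro' or 'pdb'")


def read_structure(
    path: str,
    format: str | None = None,
    group_map: dict[str, str] | None = None,
    radius_overrides: dict[str, float] | None = None,
) -> Trajectory:
    """Read a (possibly multi-frame) GRO or PDB file into a Trajectory.

    ``group_map`` maps residue-name prefixes to group tags (host/guest/
    water/ion); unmapped residues get "other".  PDB coordinates are
    converted from Angstrom to nm.
    """
    fmt = _guess_format(path, format)
    with open(path) as fh:
        lines = fh.read().splitlines()
    gmap = dict(DEFAULT_GROUP_MAP)
    if group_map:
        gmap.update(group_map)
    if fmt == "gro":
        return _read_gro(lines, gmap, radius_overrides)
    return _read_pdb(lines, gmap, radius_overrides)


def write_structure(traj: Trajectory, path: str, format: str | None = None) -> None:
    """Write a Trajectory as GRO (repeated blocks) or PDB (MODEL records)."""
    if not traj.frames:
        raise ValueError("cannot write a trajectory with no frames")
    fmt = _guess_format(path, format)
    if fmt == "gro":
        _write_gro(traj, path)
    else:
        _write_pdb(traj, path)
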