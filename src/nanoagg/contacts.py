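"""Radial distribution functions, coordination numbers, ring stacking and
guest localization.

g(r) is normalised by the 4*pi*r^2*dr shell volume and by the mean density
of the partner selection over the whole box (the common MD-tool
convention; analyses comparing against a local-density normalisation must
rescale).  The cumulative coordination function n(r) is returned alongside
and, evaluated at a cutoff that falls on a bin edge, equals the direct
neighbour count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import Frame, Trajectory, minimum_image, select, wrap_positions

__all__ = [
    "RDFResult",
    "DimerRecord",
    "LocalizationLabel",
    "rdf",
    "coordination_count",
    "detect_stacking_dimers",
    "classify_guest_localization",
    "guest_rings",
]


@dataclass(frozen=True)
class RDFResult:
    bin_centers: np.ndarray  # nm
    g: np.ndarray  # dimensionless
    n_of_r: np.ndarray  # cumulative coordination, evaluated at bin right edges
    bin_edges: np.ndarray  # nm
    bin_width: float  # nm
    pair: tuple[str, str]
    reference_density: float  # partner density, nm^-3

    def coordination(self, r: float) -> float:
        """n(r) by linear interpolation of the cumulative pair count."""
        return float(np.interp(r, np.concatenate([[0.0], self.bin_edges[1:]]),
                               np.concatenate([[0.0], self.n_of_r])))

    @property
    def first_peak(self) -> float:
        """Bin centre of the global maximum of g(r)."""
        return float(self.bin_centers[np.argmax(self.g)])

    def first_minimum(self, after: float | None = None) -> float:
        """Bin centre of the first local minimum of g(r) after the first peak."""
        start = np.argmax(self.g) if after is None else int(np.searchsorted(self.bin_centers, after))
        g = self.g
        for i in range(max(start, 1) + 1, len(g) - 1):
            if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
                return float(self.bin_centers[i])
        return float(self.bin_centers[-1])


def _frame_list(traj: Trajectory, frames) -> list[Frame]:
    if frames is None:
        return traj.frames
    return [f if isinstance(f, Frame) else traj.frames[f] for f in np.atleast_1d(frames)]


def rdf(
    traj: Trajectory,
    sel_a,
    sel_b,
    r_max: float,
    bin_width: float = 0.01,
    frames=None,
    pair_names: tuple[str, str] = ("A", "B"),
) -> RDFResult:
    """Radial distribution function g(r) between two selections.

    Minimum-image pair histogram, averaged over frames, normalised by
    shell volume and the whole-box partner density.  Shared atoms between
    the selections (including A = B) are excluded as self pairs.
    """
    a = np.asarray(sel_a, int)
    b = np.asarray(sel_b, int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rdf selections must be non-empty")
    frame_objs = _frame_list(traj, frames)
    half_box = min(float(f.box.min()) for f in frame_objs) / 2.0
    if r_max > half_box + 1e-12:
        raise ValueError(f"r_max {r_max} nm exceeds half the smallest box edge {half_box:.3f} nm")
    n_shared = len(np.intersect1d(a, b))
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    cum = np.zeros(len(edges))
    vol = 0.0
    for f in frame_objs:
        pa = wrap_positions(f.positions[a], f.box)
        pb = wrap_positions(f.positions[b], f.box)
        ta = cKDTree(pa, boxsize=f.box)
        tb = cKDTree(pb, boxsize=f.box)
        cum += ta.count_neighbors(tb, edges)
        vol += f.volume
    n_frames = len(frame_objs)
    cum -= n_shared * n_frames  # self pairs sit at distance 0
    counts = np.diff(cum)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    rho_b = len(b) * n_frames / vol  # mean partner density, nm^-3
    shell = 4.0 * np.pi * centers**2 * widths
    g = counts / (n_frames * len(a) * rho_b * shell)
    n_of_r = cum[1:] / (n_frames * len(a))
    return RDFResult(bin_centers=centers, g=g, n_of_r=n_of_r, bin_edges=edges,
                     bin_width=bin_width, pair=pair_names, reference_density=rho_b)


def coordination_count(
    traj: Trajectory,
    ref_sel,
    partner_sel,
    cutoff: float,
    frames=None,
) -> float:
    """Mean number of partner atoms within ``cutoff`` of each reference atom.

    Direct periodic neighbour count (inclusive at the cutoff), averaged
    over reference atoms and frames; self pairs are excluded.
    """
    a = np.asarray(ref_sel, int)
    b = np.asarray(partner_sel, int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("selections must be non-empty")
    shared = np.intersect1d(a, b)
    frame_objs = _frame_list(traj, frames)
    total = 0.0
    for f in frame_objs:
        pa = wrap_positions(f.positions[a], f.box)
        pb = wrap_positions(f.positions[b], f.box)
        tree = cKDTree(pb, boxsize=f.box)
        counts = tree.query_ball_point(pa, cutoff, return_length=True)
        total += counts.sum() - len(shared)  # each shared atom counts itself once
    return float(total / (len(a) * len(frame_objs)))


@dataclass(frozen=True)
class DimerRecord:
    ring_a: int  # index into rings_a
    ring_b: int  # index into rings_b
    distance: float  # centroid-centroid, nm
    angle: float  # interplanar, degrees in [0, 90]
    time: float  # ns


def _ring_plane(frame: Frame, ring: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane of a ring."""
    pos = frame.positions[np.asarray(ring, int)]
    anchor = pos[0]
    pos = anchor + minimum_image(pos - anchor, frame.box)
    centroid = pos.mean(axis=0)
    centered = pos - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-12):
        raise ValueError(f"ring {label} is degenerate (collinear atoms); no plane defined")
    return centroid, vt[2]


def detect_stacking_dimers(
    system,
    rings_a,
    rings_b,
    d_max: float = 0.5,
    angle_max: float = 30.0,
    *,
    frame: int | Frame = 0,
) -> list[DimerRecord]:
    """Pairs of rings that are close and nearly parallel (pi-stacking-like).

    Ring planes are best-fit planes (smallest principal component); a pair
    is reported when the centroid PBC distance is <= ``d_max`` and the
    interplanar angle, folded into [0, 90] degrees, is <= ``angle_max``.
    Identical rings appearing in both lists are skipped.
    """
    if isinstance(system, Trajectory):
        fr = frame if isinstance(frame, Frame) else system.frames[frame]
    else:
        fr = system
    planes_a = [_ring_plane(fr, r, f"A[{i}]") for i, r in enumerate(rings_a)]
    planes_b = [_ring_plane(fr, r, f"B[{j}]") for j, r in enumerate(rings_b)]
    sets_a = [frozenset(np.asarray(r, int).tolist()) for r in rings_a]
    sets_b = [frozenset(np.asarray(r, int).tolist()) for r in rings_b]
    records: list[DimerRecord] = []
    for i, (ca, na) in enumerate(planes_a):
        for j, (cb, nb) in enumerate(planes_b):
            if sets_a[i] == sets_b[j]:
                continue
            d = float(np.linalg.norm(minimum_image(cb - ca, fr.box)))
            if d > d_max:
                continue
            cosang = min(1.0, abs(float(np.dot(na, nb))))
            angle = float(np.degrees(np.arccos(cosang)))
            if angle <= angle_max:
                records.append(DimerRecord(ring_a=i, ring_b=j, distance=d,
                                           angle=angle, time=fr.time))
    return records


@dataclass(frozen=True)
class LocalizationLabel:
    molecule_id: int
    label: str  # interior | surface | aqueous
    burial_fraction: float  # in [0, 1]


def classify_guest_localization(
    system: Trajectory,
    host_group=None,
    guest_molecules=None,
    contact_cutoff: float = 0.7,
    interior_threshold: float = 0.9,
    aqueous_threshold: float = 0.1,
    *,
    frame: int | Frame = 0,
) -> list[LocalizationLabel]:
    """Classify each guest molecule as interior, surface or aqueous.

    The burial fraction of a guest is the fraction of its atoms that have
    at least one host atom within ``contact_cutoff`` (default 0.7 nm: the
    coarse-bead host-guest contact distance of ~0.59 nm plus slack); guests with burial
    >= ``interior_threshold`` are interior, <= ``aqueous_threshold``
    aqueous, and surface otherwise ("partially immersed, partially
    adsorbed").
    """
    fr = frame if isinstance(frame, Frame) else system.frames[frame]
    host = select(system, tag="host") if host_group is None else np.asarray(host_group, int)
    guest_atoms = select(system, tag="guest")
    if len(host) == 0 or len(guest_atoms) == 0:
        raise ValueError("need non-empty host and guest selections")
    mol_ids = np.array([system.topology[i].molecule_id for i in guest_atoms])
    wanted = np.unique(mol_ids) if guest_molecules is None else np.asarray(guest_molecules, int)
    hpos = wrap_positions(fr.positions[host], fr.box)
    tree = cKDTree(hpos, boxsize=fr.box)
    out: list[LocalizationLabel] = []
    for mid in wanted:
        atoms = guest_atoms[mol_ids == mid]
        gpos = wrap_positions(fr.positions[atoms], fr.box)
        n_contact = np.count_nonzero(
            tree.query_ball_point(gpos, contact_cutoff, return_length=True) > 0
        )
        burial = n_contact / len(atoms)
        if burial >= interior_threshold:
            label = "interior"
        elif burial <= aqueous_threshold:
            label = "aqueous"
        else:
            label = "surface"
        out.append(LocalizationLabel(molecule_id=int(mid), label=label,
                                     burial_fraction=float(burial)))
    return out


def guest_rings(traj: Trajectory, residue: str = "CUR") -> list[np.ndarray]:
    """Atom-index groups of the two phenyl-like rings of each guest molecule.

    Ring membership follows the generator's naming convention (C1..C6 and
    C7..C12 per guest); for file-based systems, supply ring definitions
    explicitly via the analysis configuration instead.
    """
    ring_a_names = {f"C{i}" for i in range(1, 7)}
    ring_b_names = {f"C{i}" for i in range(7, 13)}
    rings: list[np.ndarray] = []
    guest_atoms = select(traj, tag="guest")
    mol_ids = np.array([traj.topology[i].molecule_id for i in guest_atoms])
    for mid in np.unique(mol_ids):
        atoms = guest_atoms[mol_ids == mid]
        names = {traj.topology[i].name: i for i in atoms}
        for ring_names in (ring_a_names, ring_b_names):
            members = [names[n] for n in sorted(ring_names) if n in names]
            if len(members) >= 3:
                rings.append(np.array(members, int))
    return rings
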