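"""Gyration analysis, clustering, density slice maps and water classification.

The radius of gyration Rg = sqrt(sum_i m_i |r_i - r_cm|^2 / sum_i m_i)
tracks the compaction of a group of chains; its time series flattens once
an aggregate reaches a stable configuration, and the flattening onset is
detected from sliding-window slopes.  Density maps are 2D mass-density
slabs taken in the aggregate's principal-axis frame at the thickest point
along the slab normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import AMU_TO_G, Frame, Trajectory, make_whole, minimum_image, select, wrap_positions

__all__ = [
    "GyrationSeries",
    "ClusterAssignment",
    "DensityMap",
    "WaterClassification",
    "radius_of_gyration",
    "gyration_series",
    "detect_plateau",
    "cluster_molecules",
    "density_slice_map",
    "classify_waters",
    "unwrap_group",
    "principal_axes",
]


def _resolve(system, frame, group, masses):
    if isinstance(system, Trajectory):
        fr = frame if isinstance(frame, Frame) else system.frames[frame]
        m = system.masses if masses is None else np.asarray(masses, float)
        topo = system.topology
    else:
        raise TypeError("pass a Trajectory (topology is needed for masses/molecules)")
    idx = np.arange(fr.n_atoms) if group is None else np.asarray(group, int)
    return fr, idx, m, topo


def unwrap_group(frame: Frame, topology, group: np.ndarray) -> np.ndarray:
    """Positions of the group atoms with molecules whole and mutually unwrapped.

    Each molecule is first made whole; molecules are then shifted by whole
    periodic images so that each sits in the image nearest the centre of
    the already-placed part of the group (greedy, in molecule order).
    """
    pos = make_whole(frame, topology)
    mol_ids = np.array([topology[i].molecule_id for i in group])
    out = pos[group].copy()
    placed_sum = np.zeros(3)
    placed_n = 0
    for mid in np.unique(mol_ids):
        sel = np.nonzero(mol_ids == mid)[0]
        center = out[sel].mean(axis=0)
        if placed_n:
            ref = placed_sum / placed_n
            shift = minimum_image(center - ref, frame.box) - (center - ref)
            out[sel] += shift
            center += shift
        placed_sum += center * len(sel)
        placed_n += len(sel)
    return out


def radius_of_gyration(
    system,
    group=None,
    mass_weighted: bool = True,
    *,
    frame: int | Frame = 0,
    masses=None,
    whole: bool = True,
) -> float:
    """Radius of gyration (nm) of a group, with molecules made whole first.

    ``whole=False`` skips the PBC unwrapping and uses raw coordinates (for
    frames known to be whole already).
    """
    fr, idx, m, topo = _resolve(system, frame, group, masses)
    if len(idx) == 0:
        raise ValueError("empty group has no radius of gyration")
    pos = unwrap_group(fr, topo, idx) if whole else fr.positions[idx]
    w = m[idx] if mass_weighted else np.ones(len(idx))
    com = np.average(pos, axis=0, weights=w)
    sq = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


@dataclass(frozen=True)
class GyrationSeries:
    times: np.ndarray  # ns
    rg_values: np.ndarray  # nm
    group_description: str = ""
    mass_weighted: bool = True

    def __post_init__(self) -> None:
        if len(self.times) != len(self.rg_values):
            raise ValueError("times and rg_values length mismatch")
        if np.any(self.rg_values < 0):
            raise ValueError("rg values must be >= 0")


def gyration_series(
    traj: Trajectory,
    group=None,
    mass_weighted: bool = True,
    whole: bool = True,
    description: str = "",
) -> GyrationSeries:
    """Rg per frame of the combined group (all chains together)."""
    if not traj.frames:
        raise ValueError("trajectory has no frames")
    values = np.array([
        radius_of_gyration(traj, group, mass_weighted, frame=f, whole=whole)
        for f in traj.frames
    ])
    return GyrationSeries(times=traj.times, rg_values=values,
                          group_description=description, mass_weighted=mass_weighted)


def detect_plateau(
    series: GyrationSeries,
    window: float = 20.0,
    slope_tol: float = 0.002,
) -> float | None:
    """Earliest onset time (ns) after which the series stays flat.

    The onset is the earliest time t such that every sliding window of the
    given duration starting at or after t has a least-squares slope of
    magnitude <= ``slope_tol`` (nm/ns); None if no such time exists.
    """
    t, y = series.times, series.rg_values
    span = t[-1] - t[0]
    if window >= span:
        raise ValueError(f"window {window} ns must be shorter than the series span {span} ns")
    starts = np.nonzero(t <= t[-1] - window)[0]
    slopes = np.empty(len(starts))
    for k, i in enumerate(starts):
        sel = (t >= t[i]) & (t <= t[i] + window)
        if np.count_nonzero(sel) < 3:
            raise ValueError("fewer than 3 points per sliding window")
        tw, yw = t[sel], y[sel]
        slopes[k] = np.polyfit(tw, yw, 1)[0]
    ok = np.abs(slopes) <= slope_tol
    # suffix scan: all windows from the onset onwards must be flat
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.nonzero(suffix_ok)[0]
    if len(hits) == 0:
        return None
    return float(t[starts[hits[0]]])


@dataclass(frozen=True)
class ClusterAssignment:
    molecule_ids: np.ndarray  # unique molecule ids in the group
    labels: np.ndarray  # cluster index per molecule (0-based)
    cutoff: float  # nm
    sizes: np.ndarray  # molecules per cluster, descending

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def cluster_molecules(
    system,
    group=None,
    cutoff: float = 0.45,
    *,
    frame: int | Frame = 0,
) -> ClusterAssignment:
    """Single-linkage clustering of molecules by inter-atomic PBC contacts.

    Two molecules are linked when any pair of their atoms is within
    ``cutoff``; clusters are the connected components of that relation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    fr, idx, _, topo = _resolve(system, frame, group, None)
    mol_of_atom = np.array([topo[i].molecule_id for i in idx])
    unique_mols, mol_index = np.unique(mol_of_atom, return_inverse=True)
    n = len(unique_mols)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pos = wrap_positions(fr.positions[idx], fr.box)
    tree = cKDTree(pos, boxsize=fr.box)
    for i, j in tree.query_pairs(cutoff):
        ra, rb = find(mol_index[i]), find(mol_index[j])
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    sizes = np.sort(np.bincount(labels))[::-1]
    return ClusterAssignment(molecule_ids=unique_mols, labels=labels,
                             cutoff=cutoff, sizes=sizes)


def principal_axes(pos: np.ndarray, masses: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mass-weighted gyration-tensor eigendecomposition.

    Returns (com, eigenvalues descending, eigenvectors as columns).  Each
    eigenvector's largest-magnitude component is made positive so map
    orientations are reproducible.
    """
    com = np.average(pos, axis=0, weights=masses)
    d = pos - com
    tensor = (d * masses[:, None]).T @ d / masses.sum()
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for k in range(3):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return com, evals, evecs

_PLANE_AXES = {"xy": (0, 1, 2), "xz": (0, 2, 1), "yz": (1, 2, 0)}


@dataclass(frozen=True)
class DensityMap:
    plane: str  # in the principal-axis frame
    thickness: float  # nm
    grid_spacing: float  # nm (requested)
    values: np.ndarray  # (nx, ny) g/cm^3
    x_edges: np.ndarray  # nm, principal-frame in-plane axis 1
    y_edges: np.ndarray  # nm, principal-frame in-plane axis 2
    slab_center: float  # nm along the normal axis
    slab_mass: float  # amu, conserved by the map
    com: np.ndarray
    axes: np.ndarray  # principal axes (columns)

    @property
    def cell_volume(self) -> float:
        """nm^3 per cell (uniform; the exact volume used to form the values)."""
        return float(self.grid_spacing * self.grid_spacing * self.thickness)


def density_slice_map(
    system,
    group=None,
    plane: str = "xy",
    thickness: float = 0.8,
    grid_spacing: float = 0.1,
    *,
    frame: int | Frame = 0,
    profile_bin: float = 0.1,
) -> DensityMap:
    """2D mass-density map of a slab at the thickest point of the group.

    The group is rotated into its principal-axis frame; the slab normal is
    the axis perpendicular to the requested plane, the slab is centred at
    the maximum of the 1D mass-density profile along that normal (binned
    at ``profile_bin`` nm), and atom masses inside the slab are binned into
    2D cells.  Values are g/cm^3; summing value times cell volume returns
    the slab mass exactly.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if plane not in _PLANE_AXES:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}")
    fr, idx, m, topo = _resolve(system, frame, group, None)
    if len(idx) == 0:
        edges = np.arange(0.0, 1.0 + grid_spacing, grid_spacing)
        return DensityMap(plane=plane, thickness=thickness, grid_spacing=grid_spacing,
                          values=np.zeros((len(edges) - 1, len(edges) - 1)),
                          x_edges=edges, y_edges=edges, slab_center=0.0,
                          slab_mass=0.0, com=np.zeros(3), axes=np.eye(3))
    pos = unwrap_group(fr, topo, idx)
    w = m[idx]
    com, _, axes = principal_axes(pos, w)
    local = (pos - com) @ axes
    ax_u, ax_v, ax_n = _PLANE_AXES[plane]

    # thickest point: peak of the 1D mass profile along the slab normal
    zn = local[:, ax_n]
    nbins = max(3, int(np.ceil((zn.max() - zn.min() + 1e-9) / profile_bin)))
    hist, edges = np.histogram(zn, bins=nbins, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    slab_center = float(centers[np.argmax(hist)])

    in_slab = np.abs(zn - slab_center) <= thickness / 2.0
    if not np.any(in_slab):
        warnings.warn("density slab contains no atoms; returning an all-zero map",
                      stacklevel=2)
    u, v = local[in_slab, ax_u], local[in_slab, ax_v]
    wm = w[in_slab]
    if len(u):
        lo_u, hi_u = u.min() - grid_spacing, u.max() + grid_spacing
        lo_v, hi_v = v.min() - grid_spacing, v.max() + grid_spacing
    else:
        lo_u = lo_v = -0.5
        hi_u = hi_v = 0.5
    n_u = max(1, int(np.ceil((hi_u - lo_u) / grid_spacing)))
    n_v = max(1, int(np.ceil((hi_v - lo_v) / grid_spacing)))
    x_edges = np.linspace(lo_u, lo_u + n_u * grid_spacing, n_u + 1)
    y_edges = np.linspace(lo_v, lo_v + n_v * grid_spacing, n_v + 1)
    mass_grid = np.zeros((n_u, n_v))
    if len(u):
        iu = np.clip(np.searchsorted(x_edges, u, side="right") - 1, 0, n_u - 1)
        iv = np.clip(np.searchsorted(y_edges, v, side="right") - 1, 0, n_v - 1)
        np.add.at(mass_grid, (iu, iv), wm)
    cell_vol = grid_spacing * grid_spacing * thickness  # nm^3
    values = mass_grid * AMU_TO_G / (cell_vol * 1e-21)
    return DensityMap(plane=plane, thickness=thickness, grid_spacing=grid_spacing,
                      values=values, x_edges=x_edges, y_edges=y_edges,
                      slab_center=slab_center, slab_mass=float(wm.sum()),
                      com=com, axes=axes)


@dataclass(frozen=True)
class WaterClassification:
    water_indices: np.ndarray  # atom indices classified
    labels: np.ndarray  # "shell" | "interior" | "bulk" per water
    counts: dict[str, int]
    shell: float  # nm


def classify_waters(
    system,
    shell: float = 0.5,
    grid_spacing: float = 0.05,
    *,
    frame: int | Frame = 0,
) -> WaterClassification:
    """Classify water atoms as hydration-shell, interior-void or bulk.

    Shell: within ``shell`` nm of any host atom centre.  Interior: inside
    the flood-fill-excluded void region of the host (voids sealed off from
    the box faces).  Bulk: everything else.
    """
    from .volume import interior_void_mask

    if not isinstance(system, Trajectory):
        raise TypeError("classify_waters needs a Trajectory (group tags required)")
    fr = frame if isinstance(frame, Frame) else system.frames[frame]
    waters = select(system, tag="water")
    host = select(system, tag="host")
    if len(waters) == 0:
        warnings.warn("no water atoms present", stacklevel=2)
        return WaterClassification(water_indices=waters, labels=np.array([], dtype=object),
                                   counts={"shell": 0, "interior": 0, "bulk": 0},
                                   shell=shell)
    if len(host) == 0:
        raise ValueError("no host atoms to classify waters against")
    wpos = wrap_positions(fr.positions[waters], fr.box)
    hpos = wrap_positions(fr.positions[host], fr.box)
    tree = cKDTree(hpos, boxsize=fr.box)
    d_near, _ = tree.query(wpos)

    void, h = interior_void_mask(system, host, grid_spacing, frame=fr)
    cells = np.minimum((wpos / h).astype(int), np.array(void.shape) - 1)
    in_void = void[cells[:, 0], cells[:, 1], cells[:, 2]]

    labels = np.where(d_near <= shell, "shell", np.where(in_void, "interior", "bulk"))
    labels = labels.astype(object)
    counts = {k: int(np.count_nonzero(labels == k)) for k in ("shell", "interior", "bulk")}
    return WaterClassification(water_indices=waters, labels=labels,
                               counts=counts, shell=shell)
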