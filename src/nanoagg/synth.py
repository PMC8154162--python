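"""Synthetic molecular systems with known statistical structure.

The generators emulate the study systems analysed by this package: atactic
40-unit polystyrene-like oligomers in a coarse two-bead-per-unit
representation, coiled-chain aggregates packed to a prescribed mass
density, guest (curcumin-like) molecules either dispersed among the chains
or placed around a preformed aggregate, and an explicit hydration shell of
water points.  They also provide analytic fixtures (sphere unions, ideal
gas, cubic lattice, piecewise release curves) whose exact answers are known
in closed form, for use as test oracles.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AMU_TO_G, AtomRecord, Frame, Trajectory, wrap_positions
from .loading import ReleaseCurve

__all__ = [
    "BeadModel",
    "ChainSpec",
    "AggregateSpec",
    "SphereUnionSpec",
    "build_atactic_chain",
    "pack_aggregate",
    "sphere_union_fixture",
    "synth_release_curve",
    "ideal_gas_frame",
    "simple_cubic_frame",
    "STYRENE_UNIT_MASS",
    "GUEST_MASS",
]

STYRENE_UNIT_MASS = 104.15  # amu, one styrene monomer unit
GUEST_MASS = 368.38  # amu, curcumin
GUEST_N_BEADS = 13
GUEST_BEAD_RADIUS = 0.21  # nm


@dataclass(frozen=True)
class BeadModel:
    """Coarse two-bead-per-unit representation of a styrene unit.

    One backbone bead ("CB") and one side/phenyl bead ("CG") per unit, each
    carrying half the 104.15 amu unit mass.  The bead radius is chosen so
    that a space-filling packing of beads can tile an aggregate at melt-like
    density (~1.05 g/cm^3); smaller beads cannot reach that density with a
    union of non-overlapping spheres.
    """

    bond_length: float = 0.25  # nm
    bead_radius: float = 0.38  # nm
    min_separation: float = 0.30  # nm, non-bonded excluded-volume distance


@dataclass(frozen=True)
class ChainSpec:
    n_units: int = 40
    stereo_ratio: float = 0.5
    seed: int = 0
    bead_model: BeadModel = field(default_factory=BeadModel)

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 <= self.stereo_ratio <= 1.0:
            raise ValueError("stereo_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class AggregateSpec:
    n_chains: int = 14
    n_units: int = 40
    target_density: float = 1.05  # g/cm^3
    box: tuple[float, float, float] | None = None  # nm; auto-sized if None
    n_guests: int = 12
    guest_mode: str = "dispersed"  # dispersed | shell | none
    hydration_shell: bool = False
    n_waters: int = 800
    stereo_ratio: float = 0.5
    seed: int = 0
    bead_model: BeadModel = field(default_factory=BeadModel)
    density_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if self.guest_mode not in ("dispersed", "shell", "none"):
            raise ValueError(f"unknown guest_mode {self.guest_mode!r}")


@dataclass(frozen=True)
class SphereUnionSpec:
    centers: np.ndarray  # (n, 3) nm
    radii: np.ndarray  # (n,) nm
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, float).reshape(-1, 3))
        object.__setattr__(self, "radii", np.asarray(self.radii, float).reshape(-1))
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii length mismatch")


# ---------------------------------------------------------------------------
# chains

def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def build_atactic_chain(spec: ChainSpec) -> tuple[Trajectory, np.ndarray]:
    """Self-avoiding coarse chain with random ~1:1 stereo labels.

    Returns a single-frame Trajectory (backbone bead "CB" + side bead "CG"
    per unit, residue name STYA/STYB encoding the stereo label) and the
    label sequence as an array of "A"/"B".  Identical seeds give identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    bm = spec.bead_model
    n = spec.n_units

    backbone = np.zeros((n, 3))
    max_restarts = 200
    for attempt in range(max_restarts + 1):
        ok = True
        backbone[0] = 0.0
        for i in range(1, n):
            placed = False
            for _ in range(60):
                step = _random_unit_vectors(rng, 1)[0] * bm.bond_length
                cand = backbone[i - 1] + step
                if i >= 2:
                    d = np.linalg.norm(backbone[: i - 1] - cand, axis=1)
                    if np.min(d) < bm.min_separation:
                        continue
                backbone[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            "chain packing failed after bounded retries; use a looser bead model or larger box"
        )

    # side bead per unit, pushed away from the local backbone direction
    side = np.empty_like(backbone)
    for i in range(n):
        best = None
        best_clearance = -np.inf
        for _ in range(20):
            cand = backbone[i] + _random_unit_vectors(rng, 1)[0] * bm.bond_length
            others = np.delete(backbone, i, axis=0)
            clearance = np.min(np.linalg.norm(others - cand, axis=1)) if len(others) else 1.0
            if clearance > best_clearance:
                best_clearance = clearance
                best = cand
            if clearance >= bm.min_separation:
                break
        side[i] = best

    labels = np.where(rng.random(n) < spec.stereo_ratio, "A", "B")

    pos = np.empty((2 * n, 3))
    pos[0::2] = backbone
    pos[1::2] = side
    extent = pos.max(axis=0) - pos.min(axis=0)
    box = extent + 2.0
    pos = pos - pos.min(axis=0) + 1.0

    topology = []
    for u in range(n):
        resname = f"STY{labels[u]}"
        for k, name in enumerate(("CB", "CG")):
            topology.append(AtomRecord(
                index=2 * u + k + 1, name=name, element="C",
                mass=STYRENE_UNIT_MASS / 2.0, vdw_radius=bm.bead_radius,
                molecule_id=1, chain_label="A", group_tag="host",
                residue_name=resname,
            ))
    traj = Trajectory(topology=topology, frames=[Frame(time=0.0, positions=pos, box=box)])
    return traj, labels


# ---------------------------------------------------------------------------
# guest template

def _guest_template() -> tuple[np.ndarray, list[str]]:
    """Curcumin-like 13-bead guest: two hexagonal rings bridged by a linker.

    Ring atoms C1..C6 (containing the ring reference atom C5) and C7..C12;
    CD marks the middle of the linking chain.
    """
    ring = np.array([
        [math.cos(k * math.pi / 3), math.sin(k * math.pi / 3), 0.0] for k in range(6)
    ]) * 0.14
    offset = np.array([0.45, 0.0, 0.0])
    coords = np.vstack([ring - offset, [[0.0, 0.0, 0.0]], ring + offset])
    names = [f"C{i}" for i in range(1, 7)] + ["CD"] + [f"C{i}" for i in range(7, 13)]
    return coords, names


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# aggregate packing

def _serpentine_lattice_sites(n_sites: int, spacing: float) -> np.ndarray:
    """n_sites cubic-lattice points nearest the origin, in serpentine order.

    The serpentine (layer-by-layer, alternating row and column direction)
    ordering makes consecutive sites spatial neighbours, so consecutive
    chain segments form compact sub-coils stuck together.
    """
    # generous integer extent, then keep the n_sites closest to the origin
    r_est = (3 * n_sites / (4 * math.pi)) ** (1 / 3)
    m = int(math.ceil(r_est)) + 2
    grid = np.arange(-m, m + 1)
    ix, iy, iz = np.meshgrid(grid, grid, grid, indexing="ij")
    sites = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()])
    d2 = np.sum(sites**2, axis=1)
    order = np.lexsort((sites[:, 0], sites[:, 1], sites[:, 2], d2))
    chosen = sites[order[:n_sites]]

    # serpentine sort: z ascending, y alternating per z, x alternating per (z, y)
    key_y = np.where(chosen[:, 2] % 2 == 0, chosen[:, 1], -chosen[:, 1])
    key_x = np.where((chosen[:, 2] + chosen[:, 1]) % 2 == 0, chosen[:, 0], -chosen[:, 0])
    serp = np.lexsort((key_x, key_y, chosen[:, 2]))
    return chosen[serp].astype(float) * spacing


def _measure_density(positions, radii, masses, box, grid_spacing, mc_samples, mc_seed):
    """Aggregate density by the two available volume measures.

    Returns (probe-series density, Monte-Carlo union density).  The probe
    extrapolation slightly undershoots the volume of a ball-like body
    (linear fit to a convex V_ext(r)); the sphere union slightly overshoots
    it (surface bumps).  The packer converges their geometric mean, which
    keeps each individual measure within the stated tolerance.
    """
    # local import: volume module depends on io only, no cycle
    from .volume import mc_volume_oracle, probe_series_volume

    frame = Frame(time=0.0, positions=positions, box=box)
    group = np.arange(len(positions))
    res = probe_series_volume(
        frame, vdw_radii=radii, masses=masses, group=group,
        radii=(0.3, 0.4, 0.5, 0.6), grid_spacing=grid_spacing,
    )
    v_union = mc_volume_oracle(frame, group, n_samples=mc_samples, seed=mc_seed,
                               vdw_radii=radii)
    host_mass_g = float(np.sum(masses)) * AMU_TO_G
    d_mc = host_mass_g / (v_union * 1e-21)
    return res.density, d_mc


def pack_aggregate(spec: AggregateSpec) -> Trajectory:
    """Pack coiled chains into an aggregate of the requested mass density.

    Beads are laid on a jittered space-filling lattice inside a ball sized
    from the target density, split into per-chain serpentine paths; the
    configuration is then radially rescaled until the probe-series density
    (mass over box-minus-extrapolated-external-volume) matches the target
    within the requested tolerance.  Guests are interspersed among the chains
    (``dispersed``), placed just outside the host surface (``shell``) or
    omitted (``none``); the optional hydration shell adds water points
    within 0.5 nm of the host surface only.
    """
    rng = np.random.default_rng(spec.seed)
    bm = spec.bead_model
    n_beads = spec.n_chains * spec.n_units * 2
    host_mass = spec.n_chains * spec.n_units * STYRENE_UNIT_MASS  # amu
    v_target = host_mass * AMU_TO_G / spec.target_density * 1e21  # nm^3

    spacing = (v_target / n_beads) ** (1 / 3)
    sites = _serpentine_lattice_sites(n_beads, spacing)
    sites = sites + rng.normal(0.0, 0.04, size=sites.shape)

    r_ball = (3 * v_target / (4 * math.pi)) ** (1 / 3)
    if spec.box is not None:
        box = np.asarray(spec.box, float)
        if np.any(box < 2 * (r_ball + 1.6)):
            raise ValueError(
                f"box {spec.box} too small for an aggregate of radius ~{r_ball:.2f} nm"
            )
    else:
        edge = 2 * (r_ball + 2.2)
        box = np.array([edge, edge, edge])
    center = box / 2.0
    host_pos = sites + center

    radii = np.full(n_beads, bm.bead_radius)
    masses = np.full(n_beads, STYRENE_UNIT_MASS / 2.0)

    # radial compression/expansion until the geometric mean of the probe-series
    # and Monte-Carlo union densities matches the target: coarse-grid passes
    # first, then refinement at the analysis default grid of 0.05 nm
    mc_seed = int(np.random.default_rng(spec.seed + 1).integers(2**31))
    density = d_mc = None
    schedule = [(0.08, 200_000, 0.03)] * 3 + [(0.05, 600_000, 0.01)] * 4
    for grid, mc_n, tol in schedule:
        density, d_mc = _measure_density(host_pos, radii, masses, box, grid, mc_n, mc_seed)
        gm = math.sqrt(density * d_mc)
        ratio = gm / spec.target_density
        if abs(ratio - 1.0) <= tol and grid <= 0.05:
            break
        host_pos = center + (host_pos - center) * ratio ** (1 / 3)
    else:
        density, d_mc = _measure_density(host_pos, radii, masses, box, 0.05,
                                         600_000, mc_seed)
    for name, d in (("probe-series", density), ("union", d_mc)):
        if abs(d / spec.target_density - 1.0) > spec.density_tolerance:
            raise RuntimeError(
                f"could not pack to {spec.target_density} g/cm^3 with bead radius "
                f"{bm.bead_radius} nm ({name} density {d:.3f}); adjust the bead model"
            )

    host_dist = np.linalg.norm(host_pos - center, axis=1)
    r_max = float(host_dist.max())

    topology: list[AtomRecord] = []
    serial = 1
    for c in range(spec.n_chains):
        stereo = np.where(rng.random(spec.n_units) < spec.stereo_ratio, "A", "B")
        for u in range(spec.n_units):
            for name in ("CB", "CG"):
                topology.append(AtomRecord(
                    index=serial, name=name, element="C",
                    mass=STYRENE_UNIT_MASS / 2.0, vdw_radius=bm.bead_radius,
                    molecule_id=c + 1, chain_label=chr(ord("A") + c % 26),
                    group_tag="host", residue_name=f"STY{stereo[u]}",
                ))
                serial += 1

    positions = [host_pos]
    mol_id = spec.n_chains

    # guests
    guest_pos_all: list[np.ndarray] = []
    if spec.guest_mode != "none" and spec.n_guests > 0:
        template, names = _guest_template()
        for _ in range(spec.n_guests):
            mol_id += 1
            rot = _random_rotation(rng)
            if spec.guest_mode == "dispersed":
                # random interior location, interspersed among the chains
                while True:
                    p = rng.uniform(-1, 1, size=3)
                    if np.linalg.norm(p) <= 1.0:
                        break
                centroid = center + p * 0.8 * r_ball
            else:  # shell: just outside the host surface
                direction = _random_unit_vectors(rng, 1)[0]
                centroid = center + direction * (r_max + 0.25)
            coords = centroid + template @ rot.T
            guest_pos_all.append(coords)
            positions.append(coords)
            for k, name in enumerate(names):
                topology.append(AtomRecord(
                    index=serial, name=name, element="C",
                    mass=GUEST_MASS / GUEST_N_BEADS, vdw_radius=GUEST_BEAD_RADIUS,
                    molecule_id=mol_id, chain_label="X", group_tag="guest",
                    residue_name="CUR",
                ))
                serial += 1

    # carve local cavities: host beads are pushed out of deep overlap with
    # guest beads so guests sit in vdW-like contact with the chains rather
    # than interpenetrating them ("immersed between the coils")
    if guest_pos_all:
        from scipy.spatial import cKDTree

        gp = np.vstack(guest_pos_all)
        contact = 0.55  # nm, ~ host bead radius + guest bead radius
        for _ in range(3):
            gtree = cKDTree(gp)
            d, j = gtree.query(host_pos)
            clash = d < contact
            if not np.any(clash):
                break
            vec = host_pos[clash] - gp[j[clash]]
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            norm[norm < 1e-9] = 1e-9
            host_pos[clash] += vec / norm * (contact - d[clash])[:, None]
        positions[0] = host_pos

    # hydration shell: water points whose nearest host atom lies within
    # (bead surface, 0.5 nm]; nothing is placed inside the aggregate
    if spec.hydration_shell and spec.n_waters > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(host_pos)
        placed = 0
        waters = []
        attempts = 0
        surface_idx = np.nonzero(host_dist > 0.7 * r_max)[0]
        while placed < spec.n_waters and attempts < spec.n_waters * 200:
            attempts += 1
            anchor = host_pos[surface_idx[rng.integers(len(surface_idx))]]
            p = anchor + _random_unit_vectors(rng, 1)[0] * rng.uniform(0.40, 0.50)
            d_near, _ = tree.query(p)
            if 0.40 < d_near <= 0.50 and np.all(p > 0.1) and np.all(p < box - 0.1):
                waters.append(p)
                placed += 1
        if placed < spec.n_waters:
            raise RuntimeError("failed to place the requested hydration shell")
        positions.append(np.array(waters))
        for _ in range(placed):
            mol_id += 1
            topology.append(AtomRecord(
                index=serial, name="MW", element="O", mass=18.015,
                vdw_radius=0.14, molecule_id=mol_id, chain_label="W",
                group_tag="water", residue_name="SOL",
            ))
            serial += 1

    pos = wrap_positions(np.vstack(positions), box)
    return Trajectory(topology=topology, frames=[Frame(time=0.0, positions=pos, box=box)])


# ---------------------------------------------------------------------------
# analytic fixtures

def sphere_union_fixture(spec: SphereUnionSpec) -> Trajectory:
    """Atoms with prescribed centers and vdW radii; known union volume oracle."""
    box = np.asarray(spec.box, float)
    for i, (c, r) in enumerate(zip(spec.centers, spec.radii)):
        if np.any(c - r < 0) or np.any(c + r > box):
            raise ValueError(f"sphere {i} (center {c}, radius {r}) crosses the box boundary")
    topology = [
        AtomRecord(index=i + 1, name="SPH", element="C", mass=12.011,
                   vdw_radius=float(r), molecule_id=i + 1, group_tag="other",
                   residue_name="FIX")
        for i, r in enumerate(spec.radii)
    ]
    return Trajectory(
        topology=topology,
        frames=[Frame(time=0.0, positions=spec.centers.copy(), box=box)],
    )


def random_sphere_union(
    n_spheres: int, box_edge: float, seed: int,
    r_min: float = 0.2, r_max: float = 0.6,
) -> Trajectory:
    """Random overlapping spheres fully inside a cubic box (test fixture)."""
    rng = np.random.default_rng(seed)
    radii = rng.uniform(r_min, r_max, size=n_spheres)
    centers = np.column_stack([
        rng.uniform(radii + 1e-6, box_edge - radii - 1e-6) for _ in range(3)
    ])
    return sphere_union_fixture(SphereUnionSpec(centers, radii, (box_edge,) * 3))


def ideal_gas_frame(n: int, box_edge: float, seed: int = 0) -> Trajectory:
    """Uniform random point particles: g(r) = 1 at all r."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(n, 3))
    topology = [
        AtomRecord(index=i + 1, name="ID", element="C", mass=1.0, vdw_radius=0.0,
                   molecule_id=i + 1, group_tag="other", residue_name="GAS")
        for i in range(n)
    ]
    return Trajectory(topology=topology,
                      frames=[Frame(time=0.0, positions=pos, box=(box_edge,) * 3)])


def simple_cubic_frame(n_side: int, spacing: float) -> Trajectory:
    """Perfect simple-cubic lattice in a commensurate periodic box."""
    g = np.arange(n_side) * spacing
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    pos = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    topology = [
        AtomRecord(index=i + 1, name="LAT", element="C", mass=1.0, vdw_radius=0.0,
                   molecule_id=i + 1, group_tag="other", residue_name="LAT")
        for i in range(len(pos))
    ]
    box = (n_side * spacing,) * 3
    return Trajectory(topology=topology, frames=[Frame(time=0.0, positions=pos, box=box)])


# ---------------------------------------------------------------------------
# release curves

def synth_release_curve(
    rate: float,
    changepoint: float,
    plateau: float = 100.0,
    noise_sd: float = 0.0,
    n_points: int = 40,
    seed: int = 0,
    t_max: float = 96.0,
    tau: float | None = 12.0,
) -> ReleaseCurve:
    """Zero-order release up to a changepoint, then saturation to a plateau.

    The early phase is linear with slope ``rate`` (%/h); past the
    changepoint the curve approaches ``plateau`` as a continuous saturating
    exponential with time constant ``tau`` (h).  ``tau=None`` instead uses
    the unique slope-continuous exponential (no kink), which for small
    rate-times-changepoint relative to the plateau degenerates into a
    nearly featureless curve.  Sampling starts 15 min after t=0 and
    extends geometrically to ``t_max`` (dense early coverage, sparse late),
    then i.i.d. Gaussian noise of ``noise_sd`` (%) is added and the result
    clipped at zero.  The noiseless curve is monotone non-decreasing.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if plateau > 100.0 + 1e-9:
        raise ValueError("plateau cannot exceed 100%")
    rng = np.random.default_rng(seed)
    times = np.concatenate([[0.0], np.geomspace(0.25, t_max, n_points - 1)])
    y_cp = rate * changepoint
    if y_cp > plateau:
        raise ValueError("rate * changepoint exceeds the plateau")
    values = np.where(times <= changepoint, rate * times, 0.0)
    late = times > changepoint
    if np.any(late):
        remaining = plateau - y_cp
        if tau is not None:
            lam = 1.0 / tau
        else:
            lam = rate / remaining if remaining > 0 else 0.0
        values[late] = plateau - remaining * np.exp(-lam * (times[late] - changepoint))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
        values = np.clip(values, 0.0, None)
    return ReleaseCurve(times=times, released=values)
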