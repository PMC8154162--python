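"""Gyration, plateau detection, clustering, density maps, water classes."""

import numpy as np
import pytest

import nanoagg as na
from nanoagg.geometry import GyrationSeries
from nanoagg.io import AMU_TO_G


def _point_cloud_traj(positions, box=(20, 20, 20), masses=None, mol_ids=None):
    n = len(positions)
    masses = np.ones(n) if masses is None else masses
    mol_ids = np.arange(1, n + 1) if mol_ids is None else mol_ids
    top = [
        na.AtomRecord(index=i + 1, name="X", element="C", mass=float(masses[i]),
                      vdw_radius=0.1, molecule_id=int(mol_ids[i]), group_tag="other")
        for i in range(n)
    ]
    return na.Trajectory(top, [na.Frame(0.0, np.asarray(positions, float), box)])


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        tr = _point_cloud_traj([[1, 1, 1], [2, 1, 1]])
        assert na.radius_of_gyration(tr) == pytest.approx(0.5)

    def test_coincident_atoms(self):
        tr = _point_cloud_traj([[3, 3, 3]] * 4)
        assert na.radius_of_gyration(tr) == pytest.approx(0.0)

    def test_uniform_solid_sphere_limit(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(10**5, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (rng.random((10**5, 1)) ** (1 / 3) * 2.0) + 10.0
        tr = _point_cloud_traj(pts, mol_ids=np.ones(len(pts)))
        assert na.radius_of_gyration(tr) == pytest.approx(np.sqrt(3 / 5) * 2, rel=0.01)

    def test_empty_group_rejected(self):
        tr = _point_cloud_traj([[1, 1, 1]])
        with pytest.raises(ValueError, match="empty"):
            na.radius_of_gyration(tr, group=np.array([], int))

    def test_rigid_rotation_invariance(self, small_aggregate):
        host = na.select(small_aggregate, tag="host")
        rg0 = na.radius_of_gyration(small_aggregate, host)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        fr = small_aggregate.frames[0]
        center = fr.box / 2
        rotated = (fr.positions - center) @ rot.T + center
        tr = na.Trajectory(small_aggregate.topology,
                           [na.Frame(0.0, rotated, fr.box)])
        assert na.radius_of_gyration(tr, host) == pytest.approx(rg0, abs=1e-9)

    def test_pbc_split_molecule_made_whole(self):
        # a 2-atom molecule straddling the boundary has true extent 0.2 nm
        tr = _point_cloud_traj([[0.1, 1, 1], [4.9, 1, 1]], box=(5, 5, 5),
                               mol_ids=[1, 1])
        assert na.radius_of_gyration(tr) == pytest.approx(0.1)


class TestGyrationSeries:
    def _shrinking_traj(self, n_frames=8):
        rng = np.random.default_rng(0)
        base = rng.uniform(-1, 1, size=(30, 3))
        frames = [
            na.Frame(float(i), base * 0.9**i + 10.0, (20, 20, 20))
            for i in range(n_frames)
        ]
        top = [
            na.AtomRecord(index=i + 1, name="X", element="C", mass=1.0,
                          vdw_radius=0.1, molecule_id=1, group_tag="other")
            for i in range(30)
        ]
        return na.Trajectory(top, frames)

    def test_static_trajectory_constant(self):
        tr = self._shrinking_traj(1)
        frames = [na.Frame(float(i), tr.frames[0].positions, tr.frames[0].box)
                  for i in range(5)]
        static = na.Trajectory(tr.topology, frames)
        s = na.gyration_series(static)
        assert np.ptp(s.rg_values) == pytest.approx(0.0, abs=1e-12)

    def test_shrinking_cloud_strictly_decreasing(self):
        s = na.gyration_series(self._shrinking_traj())
        assert np.all(np.diff(s.rg_values) < 0)


class TestDetectPlateau:
    def test_constant_series_onset_at_start(self):
        t = np.arange(0, 100.0)
        s = GyrationSeries(times=t, rg_values=np.full_like(t, 2.0))
        assert na.detect_plateau(s, window=20, slope_tol=0.002) == t[0]

    def test_exponential_decay_onset_near_3tau(self):
        t = np.arange(0, 200.0)
        tau = 20.0
        s = GyrationSeries(times=t, rg_values=3.0 + 2.0 * np.exp(-t / tau))
        onset = na.detect_plateau(s, window=20, slope_tol=0.002)
        assert onset is not None
        assert abs(onset - 3 * tau) <= 2 * 20  # within 2 windows of 3 tau

    def test_steep_linear_series_has_no_plateau(self):
        t = np.arange(0, 100.0)
        s = GyrationSeries(times=t, rg_values=5.0 - 0.01 * t)
        assert na.detect_plateau(s, window=20, slope_tol=0.002) is None

    def test_time_shift_invariance(self):
        t = np.arange(0, 200.0)
        y = 3.0 + 2.0 * np.exp(-t / 20)
        s1 = GyrationSeries(times=t, rg_values=y)
        s2 = GyrationSeries(times=t + 137.0, rg_values=y)
        o1 = na.detect_plateau(s1, 20, 0.002)
        o2 = na.detect_plateau(s2, 20, 0.002)
        assert o2 - o1 == pytest.approx(137.0)

    def test_window_longer_than_span_rejected(self):
        t = np.arange(0, 10.0)
        s = GyrationSeries(times=t, rg_values=np.ones_like(t))
        with pytest.raises(ValueError):
            na.detect_plateau(s, window=50.0)


def _brute_force_clusters(positions, mol_ids, box, cutoff):
    """All-pairs union-find oracle for single-linkage molecule clustering."""
    mols = np.unique(mol_ids)
    parent = {m: m for m in mols}

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(na.minimum_image(positions[i] - positions[j], box))
            if d <= cutoff:
                ra, rb = find(mol_ids[i]), find(mol_ids[j])
                if ra != rb:
                    parent[rb] = ra
    groups = {}
    for m in mols:
        groups.setdefault(find(m), set()).add(m)
    return sorted(frozenset(g) for g in groups.values())


class TestClusterMolecules:
    def test_single_molecule(self):
        tr = _point_cloud_traj([[1, 1, 1], [1.2, 1, 1]], mol_ids=[1, 1])
        ca = na.cluster_molecules(tr, cutoff=0.45)
        assert ca.n_clusters == 1
        assert list(ca.sizes) == [1]

    def test_two_separated_molecules(self):
        tr = _point_cloud_traj([[1, 1, 1], [2.5, 1, 1]], mol_ids=[1, 2])
        ca = na.cluster_molecules(tr, cutoff=0.45)
        assert ca.n_clusters == 2

    def test_matches_brute_force_on_random_molecules(self):
        rng = np.random.default_rng(12)
        box = np.array([6.0, 6.0, 6.0])
        pos, mids = [], []
        for m in range(20):
            center = rng.uniform(0, 6, 3)
            for _ in range(4):
                pos.append(np.mod(center + rng.normal(0, 0.15, 3), box))
                mids.append(m + 1)
        pos = np.array(pos)
        mids = np.array(mids)
        tr = _point_cloud_traj(pos, box=tuple(box), mol_ids=mids)
        ca = na.cluster_molecules(tr, cutoff=0.45)
        ours = {}
        for mol, lab in zip(ca.molecule_ids, ca.labels):
            ours.setdefault(lab, set()).add(mol)
        ours = sorted(frozenset(g) for g in ours.values())
        assert ours == _brute_force_clusters(pos, mids, box, 0.45)

    def test_cluster_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 6, size=(30, 3))
        tr = _point_cloud_traj(pos, box=(6, 6, 6))
        counts = [na.cluster_molecules(tr, cutoff=c).n_clusters
                  for c in (0.3, 0.6, 1.0, 1.6, 2.4)]
        assert np.all(np.diff(counts) <= 0)


class TestDensitySliceMap:
    def test_mass_conservation_identity(self, aggregate, host_group):
        dm = na.density_slice_map(aggregate, host_group)
        recon = dm.values.sum() * dm.cell_volume * 1e-21 / AMU_TO_G
        assert recon == pytest.approx(dm.slab_mass, rel=1e-12)

    def test_uniform_block_interior_density(self):
        # anisotropic uniform-density block (distinct principal axes) with a
        # known bulk density of 1 amu per (1/rho) nm^3
        rng = np.random.default_rng(0)
        dims = np.array([4.8, 3.6, 2.4])
        rho = 16000.0  # points per nm^3 -> ~2000 points per map cell
        n = int(rho * dims.prod())
        pts = rng.uniform(0, dims, size=(n, 3)) + 3.0
        tr = _point_cloud_traj(pts, box=(12, 12, 12), mol_ids=np.ones(n))
        dm = na.density_slice_map(tr, thickness=0.8, grid_spacing=0.4)
        bulk = rho * AMU_TO_G / 1e-21
        interior = dm.values[2:-2, 2:-2]
        assert np.all(np.abs(interior - bulk) / bulk < 0.10)

    def test_empty_group_all_zero(self, small_aggregate):
        dm = na.density_slice_map(small_aggregate, group=np.array([], int))
        assert np.all(dm.values == 0)

    @pytest.mark.parametrize("plane", ["xy", "xz", "yz"])
    def test_all_planes_conserve_mass(self, small_aggregate, plane):
        host = na.select(small_aggregate, tag="host")
        dm = na.density_slice_map(small_aggregate, host, plane=plane)
        recon = dm.values.sum() * dm.cell_volume * 1e-21 / AMU_TO_G
        assert recon == pytest.approx(dm.slab_mass, rel=1e-12)


class TestClassifyWaters:
    def _system_with_waters(self, water_positions):
        host, _ = na.build_atactic_chain(na.ChainSpec(n_units=10, seed=0))
        fr = host.frames[0]
        box = (12.0, 12.0, 12.0)
        pos = np.vstack([fr.positions, water_positions])
        top = list(host.topology)
        for k in range(len(water_positions)):
            top.append(na.AtomRecord(
                index=len(top) + 1, name="MW", element="O", mass=18.015,
                vdw_radius=0.14, molecule_id=100 + k, group_tag="water",
                residue_name="SOL"))
        return na.Trajectory(top, [na.Frame(0.0, pos, box)])

    def test_near_water_is_shell_far_water_is_bulk(self):
        host, _ = na.build_atactic_chain(na.ChainSpec(n_units=10, seed=0))
        anchor = host.frames[0].positions[0]
        tr = self._system_with_waters([anchor + [0.3, 0, 0], [11.0, 11.0, 11.0]])
        wc = na.classify_waters(tr, shell=0.5, grid_spacing=0.1)
        assert list(wc.labels) == ["shell", "bulk"]

    def test_sealed_cavity_with_no_water_has_zero_interior(self, aggregate):
        wc = na.classify_waters(aggregate, shell=0.5, grid_spacing=0.08)
        assert wc.counts["interior"] == 0
        assert wc.counts["shell"] == 300

    def test_no_waters_warns(self, small_aggregate):
        with pytest.warns(UserWarning, match="no water"):
            wc = na.classify_waters(small_aggregate)
        assert wc.counts == {"shell": 0, "interior": 0, "bulk": 0}
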