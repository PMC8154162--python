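"""Probe-volume/density procedure: oracles, invariants, convergence."""

import numpy as np
import pytest

import nanoagg as na
from nanoagg.synth import SphereUnionSpec, random_sphere_union
from nanoagg.volume import GridError, extrapolate_to_zero, interior_void_mask


def _hollow_shell(radius=1.5, bead_r=0.25, box=6.0):
    """Sealed spherical shell of beads: known interior cavity."""
    pts = []
    n_theta = int(np.pi * radius / (bead_r * 0.9))
    for i in range(n_theta + 1):
        theta = np.pi * i / n_theta
        n_phi = max(1, int(2 * np.pi * radius * np.sin(theta) / (bead_r * 0.9)))
        for j in range(n_phi):
            phi = 2 * np.pi * j / n_phi
            pts.append([
                radius * np.sin(theta) * np.cos(phi),
                radius * np.sin(theta) * np.sin(phi),
                radius * np.cos(theta),
            ])
    pts = np.array(pts) + box / 2
    top = [
        na.AtomRecord(index=i + 1, name="SH", element="C", mass=12.0,
                      vdw_radius=bead_r, molecule_id=1, group_tag="host",
                      residue_name="PSX")
        for i in range(len(pts))
    ]
    return na.Trajectory(top, [na.Frame(0.0, pts, (box, box, box))])


class TestExternalVolume:
    def test_empty_group_gives_box_volume(self):
        tr = random_sphere_union(5, 4.0, seed=0)
        v = na.external_volume(tr, group=np.array([], dtype=int),
                               probe_radius=0.0, grid_spacing=0.05)
        assert v == pytest.approx(64.0)

    def test_single_atom_closed_form(self):
        tr = na.sphere_union_fixture(SphereUnionSpec([[2, 2, 2]], [0.2], (4, 4, 4)))
        v = na.external_volume(tr, probe_radius=0.0, grid_spacing=0.02)
        cell = 0.02**3
        assert abs((64.0 - v) - 4 / 3 * np.pi * 0.2**3) <= 2 * cell + 1e-3

    def test_grid_too_coarse_rejected(self):
        tr = random_sphere_union(3, 4.0, seed=1)
        with pytest.raises(GridError, match="coarse"):
            na.external_volume(tr, probe_radius=0.0, grid_spacing=1.0)

    def test_monotone_in_probe_radius(self, aggregate, host_group):
        fr = aggregate.frames[0]
        from nanoagg.volume import gap_field

        F, h = gap_field(fr, aggregate.vdw_radii, host_group, 0.06, max_probe=0.8)
        vols = [
            na.external_volume(fr, host_group, r, 0.06,
                               vdw_radii=aggregate.vdw_radii, _field=(F, h))
            for r in (0.2, 0.3, 0.45, 0.6, 0.8)
        ]
        cell = 0.06**3
        assert np.all(np.diff(vols) <= cell)

    def test_flood_fill_excludes_sealed_cavity(self):
        tr = _hollow_shell()
        with_fill = na.external_volume(tr, probe_radius=0.0, grid_spacing=0.05)
        without = na.external_volume(tr, probe_radius=0.0, grid_spacing=0.05,
                                     exclude_voids=False)
        cavity = without - with_fill
        # cavity approximately the inner ball of radius (shell R - bead r)
        inner = 4 / 3 * np.pi * (1.5 - 0.25) ** 3
        assert cavity == pytest.approx(inner, rel=0.15)

    def test_flood_fill_matches_plain_on_convex_body(self):
        """For a void-free convex body the flood fill changes nothing."""
        tr = na.sphere_union_fixture(SphereUnionSpec([[3, 3, 3]], [1.2], (6, 6, 6)))
        a = na.external_volume(tr, probe_radius=0.3, grid_spacing=0.04)
        b = na.external_volume(tr, probe_radius=0.3, grid_spacing=0.04,
                               exclude_voids=False)
        assert a == pytest.approx(b, abs=0.04**3 * 2)


class TestExtrapolation:
    def test_exactly_linear_series_recovered_to_machine_precision(self):
        r = np.array([0.3, 0.4, 0.5, 0.6, 0.8])
        v = 100.0 - 8.0 * r
        intercept, coeffs, r2 = extrapolate_to_zero(r, v)
        assert intercept == pytest.approx(100.0, abs=1e-10)
        assert coeffs[0] == pytest.approx(-8.0, abs=1e-10)
        assert r2 == pytest.approx(1.0)

    def test_quadratic_fit_recovers_quadratic(self):
        r = np.array([0.3, 0.4, 0.5, 0.6])
        v = 50.0 - 3.0 * r + 2.0 * r**2
        intercept, _, _ = extrapolate_to_zero(r, v, degree=2)
        assert intercept == pytest.approx(50.0, abs=1e-9)

    def test_bad_radius_series_rejected(self, small_aggregate):
        with pytest.raises(ValueError, match="increasing"):
            na.probe_series_volume(small_aggregate, radii=(0.5, 0.4, 0.3))
        with pytest.raises(ValueError):
            na.probe_series_volume(small_aggregate, radii=(0.3, 0.4))


class TestProbeSeries:
    def test_density_recovery_on_packed_aggregate(self, aggregate, host_group):
        res = na.probe_series_volume(aggregate, host_group,
                                     radii=(0.3, 0.4, 0.5, 0.6), grid_spacing=0.05)
        assert res.density == pytest.approx(1.05, rel=0.05)
        assert res.fit_r_squared > 0.99

    def test_scaling_oracle(self):
        """Doubling all coordinates and the box scales the volume by 8."""
        tr = random_sphere_union(12, 4.0, seed=5)
        fr = tr.frames[0]
        big_top = [
            na.AtomRecord(index=a.index, name=a.name, element=a.element,
                          mass=a.mass, vdw_radius=a.vdw_radius * 2,
                          molecule_id=a.molecule_id, group_tag=a.group_tag,
                          residue_name=a.residue_name)
            for a in tr.topology
        ]
        big = na.Trajectory(big_top, [na.Frame(0.0, fr.positions * 2, fr.box * 2)])
        r1 = na.probe_series_volume(tr, radii=(0.15, 0.2, 0.25, 0.3), grid_spacing=0.04)
        r2 = na.probe_series_volume(big, radii=(0.3, 0.4, 0.5, 0.6), grid_spacing=0.08)
        assert r2.aggregate_volume == pytest.approx(8 * r1.aggregate_volume, rel=0.02)

    def test_grid_convergence(self):
        """Halving the grid spacing changes the occupied volume by < 1%."""
        tr = na.sphere_union_fixture(SphereUnionSpec([[3, 3, 3]], [1.0], (6, 6, 6)))
        box_vol = tr.frames[0].volume
        for probe in (0.0, 0.4):
            coarse = box_vol - na.external_volume(tr, probe_radius=probe,
                                                  grid_spacing=0.06)
            fine = box_vol - na.external_volume(tr, probe_radius=probe,
                                                grid_spacing=0.03)
            assert fine == pytest.approx(coarse, rel=0.01)


class TestMCOracle:
    def test_unit_sphere(self):
        tr = na.sphere_union_fixture(SphereUnionSpec([[2.5, 2.5, 2.5]], [1.0], (5, 5, 5)))
        n = 10**6
        v = na.mc_volume_oracle(tr, n_samples=n, seed=3)
        exact = 4 / 3 * np.pi
        p = exact / 125.0
        sigma = 125.0 * np.sqrt(p * (1 - p) / n)
        assert abs(v - exact) <= 3 * sigma

    def test_empty_group(self):
        tr = random_sphere_union(4, 4.0, seed=2)
        assert na.mc_volume_oracle(tr, group=np.array([], int), n_samples=10**5) == 0.0

    def test_cross_method_on_void_free_fixture(self):
        tr = random_sphere_union(8, 4.0, seed=7)
        fr = tr.frames[0]
        grid_union = fr.volume - na.external_volume(
            tr, probe_radius=0.0, grid_spacing=0.03, exclude_voids=False)
        mc = na.mc_volume_oracle(tr, n_samples=10**6, seed=8)
        assert grid_union == pytest.approx(mc, rel=0.01)

    def test_sample_floor_enforced(self):
        tr = random_sphere_union(3, 4.0, seed=9)
        with pytest.raises(ValueError):
            na.mc_volume_oracle(tr, n_samples=10**4)


class TestFrameAveraged:
    def _static_traj(self, jitter=0.0, n_frames=5, seed=0):
        # compact cluster of spheres near the box centre (aggregate-like)
        rng0 = np.random.default_rng(11)
        centers = 2.5 + rng0.normal(0, 0.45, size=(60, 3))
        radii = rng0.uniform(0.3, 0.45, 60)
        base = na.sphere_union_fixture(SphereUnionSpec(centers, radii, (5, 5, 5)))
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(n_frames):
            pos = base.frames[0].positions.copy()
            if jitter:
                pos = pos + rng.normal(0, jitter, pos.shape)
            frames.append(na.Frame(float(i), pos, base.frames[0].box))
        return na.Trajectory(base.topology, frames)

    def test_identical_frames_zero_sd(self):
        traj = self._static_traj()
        res = na.frame_averaged_density(traj, radii=(0.2, 0.3, 0.4), grid_spacing=0.05)
        assert res.volume_sd == pytest.approx(0.0, abs=1e-9)

    def test_jitter_stability(self):
        clean = na.frame_averaged_density(self._static_traj(), radii=(0.2, 0.3, 0.4),
                                          grid_spacing=0.05)
        noisy = na.frame_averaged_density(self._static_traj(jitter=0.01, seed=4),
                                          radii=(0.2, 0.3, 0.4), grid_spacing=0.05)
        assert noisy.volume_mean == pytest.approx(clean.volume_mean, rel=0.02)

    def test_overlong_window_rejected(self):
        traj = self._static_traj()
        with pytest.raises(ValueError, match="window"):
            na.frame_averaged_density(traj, radii=(0.2, 0.3, 0.4),
                                      grid_spacing=0.05, window=100.0)
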