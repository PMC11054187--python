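"""Superposition, RMSD/RMSF, Rg, SASA, hydrogen bonds, distribution peaks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdbind.metrics import (HBondSpec, detect_hbonds, kabsch_superpose,
                            radius_of_gyration, rmsd_series, rmsf, sasa,
                            series_summary)

from conftest import make_ensemble, make_topology


class TestKabsch:
    def test_identical_frames(self, rng):
        x = rng.normal(size=(6, 3))
        r, t, rmsd, aligned = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-8)

    def test_translation_only(self, rng):
        x = rng.normal(size=(5, 3))
        _, _, rmsd, _ = kabsch_superpose(x + np.array([3.0, -1.0, 7.0]), x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_constructed_rotation_recovered(self):
        """Asymmetric 4-point set rotated 37 deg about z: exact recovery."""
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0.5, 0.3, 1.7]])
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        mobile = x @ rot.T
        r, _, rmsd, _ = kabsch_superpose(mobile, x)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(r, rot.T, atol=1e-8)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-8)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(4), np.zeros(4), np.zeros(4)]).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsd:
    def test_copies_of_reference_are_zero(self, rng):
        ref = rng.normal(scale=5, size=(8, 3))
        ens = make_ensemble(np.stack([ref] * 4))
        out = rmsd_series(ens, ref, selection="calpha")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_gaussian_ensemble_closed_form(self, rng):
        """Many-atom sigma-Gaussian frames: mean RMSD -> sigma*sqrt(3)."""
        sigma = 0.3
        ref = rng.normal(scale=10, size=(300, 3))
        ens = make_ensemble(ref[None] + rng.normal(scale=sigma, size=(60, 300, 3)))
        out = rmsd_series(ens, ref, selection="calpha")
        assert out.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_global_rotation_invariance(self, rng):
        ref = rng.normal(scale=5, size=(10, 3))
        frames = ref[None] + rng.normal(scale=0.4, size=(5, 10, 3))
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        a = rmsd_series(make_ensemble(frames), ref, selection="calpha").values
        b = rmsd_series(make_ensemble(frames @ rot.T), ref, selection="calpha").values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_empty_selection_rejected(self, rng):
        ens = make_ensemble(rng.normal(size=(2, 5, 3)),
                            make_topology(5, atom_name="CB"))
        with pytest.raises(ValueError, match="calpha"):
            rmsd_series(ens, ens.coords[0], selection="calpha")


class TestRmsf:
    def test_identical_frames_zero(self, rng):
        x = rng.normal(scale=5, size=(6, 3))
        ens = make_ensemble(np.stack([x] * 4))
        np.testing.assert_allclose(rmsf(ens), 0.0, atol=1e-10)

    def test_alternating_atom_closed_form(self, rng):
        """One atom at +/-d along x about fixed others: RMSF exactly d."""
        base = rng.normal(scale=5, size=(6, 3))
        d = 0.7
        up, down = base.copy(), base.copy()
        up[0, 0] += d
        down[0, 0] -= d
        ens = make_ensemble(np.stack([up, down, up, down]))
        out = rmsf(ens, superpose=False)
        assert out[0] == pytest.approx(d, abs=1e-12)
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_isotropic_gaussian_closed_form(self, rng):
        sigma = 0.25
        base = rng.normal(scale=8, size=(150, 3))
        ens = make_ensemble(base[None] + rng.normal(scale=sigma, size=(400, 150, 3)))
        out = rmsf(ens, superpose=False)
        assert out.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            rmsf(make_ensemble(rng.normal(size=(1, 5, 3))))


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        topo = make_topology(2)
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords, topo) == pytest.approx(1.0)

    def test_coincident_atoms(self):
        topo = make_topology(3)
        assert radius_of_gyration(np.zeros((3, 3)), topo) == 0.0

    def test_uniform_ring(self):
        n, rho = 60, 4.2
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        coords = np.column_stack([rho * np.cos(theta), rho * np.sin(theta),
                                  np.zeros(n)])
        assert radius_of_gyration(coords, make_topology(n)) == pytest.approx(rho)


class TestSasa:
    def _topo(self, n, radius=1.8):
        topo = make_topology(n)
        topo.born_radius = np.full(n, radius)
        return topo

    def test_single_sphere_closed_form(self):
        total, _ = sasa(np.zeros((1, 3)), self._topo(1, 1.8))
        assert total == pytest.approx(4 * np.pi * (1.8 + 1.4) ** 2, rel=0.01)

    def test_distant_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        total, per_atom = sasa(coords, self._topo(2, 1.5))
        single = 4 * np.pi * (1.5 + 1.4) ** 2
        assert total == pytest.approx(2 * single, rel=0.01)
        np.testing.assert_allclose(per_atom, single, rtol=0.01)

    def test_two_overlapping_spheres_match_dense_oracle(self):
        """Shrake-Rupley vs an independent high-resolution point oracle."""
        r, probe, sep = 1.8, 1.4, 2.5
        coords = np.array([[0.0, 0, 0], [sep, 0, 0]])
        total, _ = sasa(coords, self._topo(2, r), probe=probe, n_points=960)

        # dense-grid oracle: 200k quasi-random points per sphere
        rng = np.random.default_rng(0)
        big = rng.normal(size=(200_000, 3))
        big /= np.linalg.norm(big, axis=1, keepdims=True)
        rr = r + probe
        oracle = 0.0
        for center, other in ((coords[0], coords[1]), (coords[1], coords[0])):
            pts = center + rr * big
            frac = (np.linalg.norm(pts - other, axis=1) >= rr).mean()
            oracle += frac * 4 * np.pi * rr ** 2
        assert total == pytest.approx(oracle, rel=0.02)

    def test_monotone_under_approach(self):
        areas = []
        for sep in (8.0, 5.0, 3.0, 1.0):
            coords = np.array([[0.0, 0, 0], [sep, 0, 0]])
            areas.append(sasa(coords, self._topo(2))[0])
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            sasa(np.zeros((1, 3)), make_topology(1))

    def test_biotite_cross_check(self):
        """Independent implementation agreement on a small random cluster."""
        import biotite.structure as struc
        rng = np.random.default_rng(5)
        n = 8
        coords = rng.uniform(0, 6, size=(n, 3))
        radius = 1.7
        total, _ = sasa(coords, self._topo(n, radius), n_points=960)
        atoms = struc.AtomArray(n)
        atoms.coord = coords.astype(np.float32)
        atoms.element = np.array(["C"] * n)
        atoms.atom_name = np.array(["CA"] * n)
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.array(["GLY"] * n)
        atoms.chain_id = np.array(["A"] * n)
        atoms.hetero = np.zeros(n, dtype=bool)
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960,
                         vdw_radii=np.full(n, radius)).sum()
        assert total == pytest.approx(ref, rel=0.02)


class TestHBonds:
    def _geometry(self, da_dist, dha_angle_deg):
        """Donor at origin, H on +x; acceptor at the requested D..A distance
        and D-H...A angle (measured at the hydrogen)."""
        h = np.array([1.0, 0.0, 0.0])
        # D-H points along -x from H, so a D-H...A angle of phi puts H->A at
        # an angle of 180 - phi from +x
        theta = np.radians(180.0 - dha_angle_deg)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])

        lo, hi = 0.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(h + mid * direction) < da_dist:
                lo = mid
            else:
                hi = mid
        a = h + 0.5 * (lo + hi) * direction
        coords = np.stack([np.zeros(3), h, a])[None]
        return make_ensemble(coords, make_topology(3))

    @pytest.mark.parametrize("dist,angle,present", [
        (2.9, 160.0, True),        # inside both criteria
        (3.6, 170.0, False),       # distance violated regardless of angle
        (2.9, 100.0, False),       # angle violated
        (3.49, 121.0, True),       # just inside both strict bounds
    ])
    def test_geometric_criteria(self, dist, angle, present):
        ens = self._geometry(dist, angle)
        spec = HBondSpec(donor=0, hydrogen=1, acceptor=2)
        result = detect_hbonds(ens, [spec])[0]
        assert bool(result.present[0]) is present

    def test_occupancy_definition(self, rng):
        """Present in 87 of 100 frames -> occupancy exactly 87.0%."""
        near = self._geometry(2.9, 160.0).coords[0]
        far = self._geometry(5.0, 160.0).coords[0]
        frames = np.stack([near] * 87 + [far] * 13)
        ens = make_ensemble(frames, make_topology(3))
        result = detect_hbonds(ens, [HBondSpec(0, 1, 2)])[0]
        assert result.occupancy == 87.0
        assert 0.0 <= result.occupancy <= 100.0

    def test_occupancy_monotone_in_distance_cutoff(self, rng):
        frames = np.stack([self._geometry(d, 150.0).coords[0]
                           for d in rng.uniform(2.5, 4.5, size=40)])
        ens = make_ensemble(frames, make_topology(3))
        occ = [detect_hbonds(ens, [HBondSpec(0, 1, 2, distance_cutoff=c)])[0].occupancy
               for c in (4.0, 3.5, 3.0)]
        assert occ[0] >= occ[1] >= occ[2]

    def test_missing_atom_rejected(self, rng):
        ens = make_ensemble(rng.normal(size=(1, 3, 3)))
        with pytest.raises(ValueError, match="missing atom"):
            detect_hbonds(ens, [HBondSpec(0, 1, 5)])


class TestSeriesSummary:
    def test_bimodal_peaks_recovered(self, rng):
        values = np.concatenate([rng.normal(1.7, 0.1, 4000),
                                 rng.normal(2.3, 0.1, 4000)])
        out = series_summary(values, n_bins=50)
        assert len(out.peaks) == 2
        assert out.peaks[0] == pytest.approx(1.7, abs=0.1)
        assert out.peaks[1] == pytest.approx(2.3, abs=0.1)

    def test_constant_series_single_peak(self):
        out = series_summary(np.full(10, 3.3), n_bins=5)
        assert len(out.peaks) == 1

    def test_counts_conserved(self, rng):
        values = rng.normal(size=123)
        out = series_summary(values, n_bins=20)
        assert out.counts.sum() == 123
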