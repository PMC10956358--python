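import math

import numpy as np
import pytest

from qsarkit.traj import (
    BONDI_RADII,
    KB_KCAL,
    Trajectory,
    fel_grid,
    hbond_count,
    pca_coords,
    radius_of_gyration,
    read_pdb_models,
    read_xyz,
    rmsd_series,
    rmsf,
    sasa,
    superpose,
    write_pdb_models,
    write_xyz,
)
from qsarkit.synthetic import gen_trajectory


def random_rigid_motion(rng):
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(0, 5, 3)
    return Q, t


class TestSuperpose:
    def test_identity_on_self(self, rng):
        coords = rng.standard_normal((10, 3))
        R, t, fitted = superpose(coords, coords)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_recovers_rigid_motion(self, rng):
        coords = rng.standard_normal((15, 3))
        Q, t = random_rigid_motion(rng)
        moved = coords @ Q.T + t
        _, _, fitted = superpose(moved, coords)
        assert np.sqrt(np.mean(np.sum((fitted - coords) ** 2, axis=1))) < 1e-8

    def test_rotation_is_proper(self, rng):
        for _ in range(10):
            a = rng.standard_normal((8, 3))
            b = rng.standard_normal((8, 3))
            R, _, _ = superpose(a, b)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_matches_mdanalysis_rotation(self, rng):
        mda_align = pytest.importorskip("MDAnalysis.analysis.align")
        for _ in range(20):
            a = rng.standard_normal((12, 3))
            b = rng.standard_normal((12, 3))
            w = rng.uniform(1, 16, 12)
            _, _, fitted = superpose(a, b, weights=w)
            ours = math.sqrt(float(np.sum(w * np.sum((fitted - b) ** 2, axis=1)) / w.sum()))
            ac = a - np.average(a, axis=0, weights=w)
            bc = b - np.average(b, axis=0, weights=w)
            _, ref_rmsd = mda_align.rotation_matrix(ac, bc, weights=w)
            assert ours == pytest.approx(ref_rmsd, abs=1e-6)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(line, line + 1.0)


class TestRMSD:
    def test_static_trajectory_zero(self, rng):
        ref = rng.standard_normal((10, 3))
        traj = Trajectory(np.repeat(ref[None], 5, axis=0))
        np.testing.assert_allclose(rmsd_series(traj, ref), 0.0, atol=1e-12)

    def test_single_atom_displacement_no_fit(self):
        ref = np.random.default_rng(0).standard_normal((10, 3))
        frame = ref.copy()
        frame[3, 0] += 2.0
        traj = Trajectory(frame[None])
        out = rmsd_series(traj, ref, mass_weighted=False, fit=False)
        assert out[0] == pytest.approx(2.0 / math.sqrt(10), abs=1e-12)
        assert out[0] == pytest.approx(0.6325, abs=1e-4)

    def test_fit_invariant_to_rigid_motion(self, rng):
        traj, ref, _ = gen_trajectory(20, 12, jitter_sd=0.4, seed=8)
        base = rmsd_series(traj, ref)
        Q, t = random_rigid_motion(rng)
        moved = Trajectory(traj.coords @ Q.T + t, masses=traj.masses)
        np.testing.assert_allclose(rmsd_series(moved, ref), base, atol=1e-8)

    def test_matches_mdanalysis(self):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis import rms

        traj, ref, _ = gen_trajectory(25, 10, jitter_sd=0.5, seed=3)
        masses = np.random.default_rng(1).uniform(1, 16, 10)
        traj = Trajectory(traj.coords, masses=masses)
        ours = rmsd_series(traj, ref)
        u = mda.Universe.empty(10, trajectory=True)
        u.add_TopologyAttr("masses", masses)
        u.load_new(traj.coords.astype(np.float64), format="memory")
        r = mda.Universe.empty(10, trajectory=True)
        r.add_TopologyAttr("masses", masses)
        r.load_new(ref[None].astype(np.float64), format="memory")
        analysis = rms.RMSD(u, r, weights="mass").run()
        np.testing.assert_allclose(ours, analysis.results.rmsd[:, 2], atol=1e-5)

    def test_atom_mismatch_rejected(self):
        traj, ref, _ = gen_trajectory(3, 5, 0.1, seed=0)
        with pytest.raises(ValueError):
            rmsd_series(traj, ref[:4])


class TestRMSF:
    def test_static_zero(self, rng):
        ref = rng.standard_normal((8, 3))
        traj = Trajectory(np.repeat(ref[None], 4, axis=0))
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_gaussian_jitter_closed_form(self):
        # i.i.d. jitter sd sigma per coordinate -> RMSF ~= sigma*sqrt(3)
        sigma = 0.5
        traj, _, _ = gen_trajectory(10_000, 8, jitter_sd=sigma, seed=4)
        vals = rmsf(traj, align_first=False)
        np.testing.assert_allclose(vals, sigma * math.sqrt(3), rtol=0.05)

    def test_matches_mdanalysis(self):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis import rms

        traj, _, _ = gen_trajectory(50, 12, jitter_sd=0.3, seed=5)
        ours = rmsf(traj, align_first=False)
        u = mda.Universe.empty(12, trajectory=True)
        u.load_new(traj.coords.astype(np.float64), format="memory")
        ref_vals = rms.RMSF(u.atoms).run().results.rmsf
        np.testing.assert_allclose(ours, ref_vals, atol=1e-5)

    def test_translation_invariance(self):
        traj, _, _ = gen_trajectory(30, 6, jitter_sd=0.2, seed=6)
        shifted = Trajectory(traj.coords + np.array([10.0, -4.0, 2.0]), masses=traj.masses)
        np.testing.assert_allclose(rmsf(shifted), rmsf(traj), atol=1e-8)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(Trajectory(np.zeros((1, 4, 3))))


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        traj = Trajectory(np.zeros((3, 1, 3)))
        np.testing.assert_allclose(radius_of_gyration(traj), 0.0)

    def test_symmetric_pair(self):
        d = 2.5
        coords = np.array([[[d, 0, 0], [-d, 0, 0]]])
        traj = Trajectory(coords, masses=np.array([1.0, 1.0]))
        assert radius_of_gyration(traj)[0] == pytest.approx(d)

    def test_matches_mdanalysis(self):
        mda = pytest.importorskip("MDAnalysis")
        traj, _, _ = gen_trajectory(10, 15, jitter_sd=0.5, seed=7)
        masses = np.random.default_rng(2).uniform(1, 16, 15)
        traj = Trajectory(traj.coords, masses=masses)
        ours = radius_of_gyration(traj)
        u = mda.Universe.empty(15, trajectory=True)
        u.add_TopologyAttr("masses", masses)
        u.load_new(traj.coords.astype(np.float64), format="memory")
        ref_vals = [u.atoms.radius_of_gyration() for _ in u.trajectory]
        np.testing.assert_allclose(ours, ref_vals, atol=1e-5)

    def test_translation_invariance(self):
        traj, _, _ = gen_trajectory(5, 8, jitter_sd=0.3, seed=9)
        shifted = Trajectory(traj.coords + 100.0, masses=traj.masses)
        np.testing.assert_allclose(
            radius_of_gyration(shifted), radius_of_gyration(traj), atol=1e-8
        )


class TestHbonds:
    def _triple(self, ha_dist, angle_deg):
        """Donor at origin, H at (1,0,0), acceptor placed at ha_dist from H
        such that the D-H...A angle equals angle_deg."""
        theta = math.radians(180.0 - angle_deg)
        a = np.array([1.0 + ha_dist * math.cos(theta), ha_dist * math.sin(theta), 0.0])
        coords = np.array([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], a]])
        return Trajectory(coords)

    def test_linear_bond_counted(self):
        traj = self._triple(2.0, 180.0)
        counts, occ = hbond_count(traj, donors=[0], hydrogens=[1], acceptors=[2])
        assert counts[0] == 1
        assert occ[(0, 1, 2)] == 1.0

    def test_bent_rejected(self):
        counts, _ = hbond_count(self._triple(2.0, 120.0), [0], [1], [2])
        assert counts[0] == 0

    def test_far_rejected(self):
        counts, _ = hbond_count(self._triple(3.6, 180.0), [0], [1], [2])
        assert counts[0] == 0

    def test_boundary_just_inside_angle_window(self):
        counts, _ = hbond_count(self._triple(2.0, 150.5), [0], [1], [2])
        assert counts[0] == 1

    def test_donor_acceptor_mode(self):
        # H...A = 3.0 but D...A = 4.0: counted in H-A mode, not in D-A mode
        traj = self._triple(3.0, 180.0)
        ha, _ = hbond_count(traj, [0], [1], [2], distance_mode="hydrogen-acceptor")
        da, _ = hbond_count(traj, [0], [1], [2], distance_mode="donor-acceptor")
        assert ha[0] == 1 and da[0] == 0

    def test_unpaired_hydrogen_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            hbond_count(self._triple(2.0, 180.0), donors=[], hydrogens=[1], acceptors=[2])


class TestSASA:
    def test_isolated_atom_analytic(self):
        total, per_atom = sasa(np.zeros((1, 3)), [1.7])
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_disjoint_spheres_additive(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        total, per_atom = sasa(coords, [1.7, 1.52])
        expected = 4 * math.pi * ((1.7 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
        assert total == pytest.approx(expected, rel=0.01)

    def test_buried_atom_zero(self):
        # small atom fully inside a big one
        coords = np.zeros((2, 3))
        total, per_atom = sasa(coords, [0.5, 5.0])
        assert per_atom[0] == 0.0

    def test_matches_biotite_on_random_clusters(self):
        struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(10)
        for _ in range(3):
            n = 30
            coords = rng.uniform(0, 8, size=(n, 3))
            radii = rng.choice([1.2, 1.52, 1.55, 1.7], size=n)
            ours, _ = sasa(coords, radii, n_sphere_points=960)
            arr = struc.AtomArray(n)
            arr.coord = coords
            arr.element = np.array(["C"] * n)
            ref = float(np.nansum(struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                                             point_number=960)))
            assert ours == pytest.approx(ref, rel=0.02)

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), [float("nan")])


class TestPCA:
    def test_eigenvalues_sorted(self):
        traj, _, _ = gen_trajectory(40, 6, jitter_sd=0.5, seed=11)
        eigvals, _, _ = pca_coords(traj)
        assert np.all(np.diff(eigvals) <= 1e-12)

    def test_planar_motion_two_components(self):
        # oscillation confined to the xy-plane of one atom
        rng = np.random.default_rng(12)
        base = rng.standard_normal((5, 3))
        frames = []
        for t in range(60):
            f = base.copy()
            f[0, 0] += math.cos(0.3 * t)
            f[0, 1] += math.sin(0.3 * t) * 0.5
            frames.append(f)
        traj = Trajectory(np.array(frames))
        eigvals, _, _ = pca_coords(traj, align_first=False)
        assert eigvals[2] <= 1e-10 * eigvals[0]

    def test_variance_conservation(self):
        traj, _, _ = gen_trajectory(30, 8, jitter_sd=0.4, seed=13)
        eigvals, _, _ = pca_coords(traj, align_first=False)
        flat = traj.coords.reshape(30, -1)
        total_var = float(np.sum(np.var(flat, axis=0, ddof=1)))
        assert np.sum(eigvals) == pytest.approx(total_var, abs=1e-8)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            pca_coords(Trajectory(np.zeros((2, 4, 3))))


class TestFEL:
    def test_occupied_minimum_is_zero(self, rng):
        grid = fel_grid(rng.standard_normal(500), rng.standard_normal(500))
        assert np.nanmin(grid.delta_g) == 0.0

    def test_probabilities_sum_to_one(self, rng):
        grid = fel_grid(rng.standard_normal(300), rng.standard_normal(300))
        assert grid.prob.sum() == pytest.approx(1.0)

    def test_two_basin_minima(self):
        traj, _, labels = gen_trajectory(2000, 5, jitter_sd=0.3, basins=2, seed=14)
        _, _, proj = pca_coords(traj, align_first=False, n_components=2)
        grid = fel_grid(proj[:, 0], proj[:, 1], bins=30)
        # split the PC1 axis between the two basin means: each side must hold
        # a near-zero well, and the wells must differ by < 0.2 kT
        mid = 0.5 * (proj[labels == 0, 0].mean() + proj[labels == 1, 0].mean())
        centers = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        left = np.nanmin(grid.delta_g[centers < mid, :])
        right = np.nanmin(grid.delta_g[centers >= mid, :])
        kT = KB_KCAL * 310.0
        assert abs(left - right) < 0.2 * kT
        assert min(left, right) == 0.0

    def test_temperature_linearity(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        g1 = fel_grid(x, y, temperature_K=310.0)
        g2 = fel_grid(x, y, temperature_K=620.0)
        mask = ~np.isnan(g1.delta_g)
        np.testing.assert_allclose(g2.delta_g[mask], 2 * g1.delta_g[mask], atol=1e-12)

    def test_empty_bins_masked_not_inf(self, rng):
        grid = fel_grid(rng.standard_normal(50), rng.standard_normal(50), bins=40)
        assert np.isnan(grid.delta_g[grid.prob == 0]).all()
        assert not np.isinf(grid.delta_g[~np.isnan(grid.delta_g)]).any()

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fel_grid(np.ones(100), np.arange(100.0))


class TestTrajectoryIO:
    def test_xyz_roundtrip(self, tmp_path):
        traj, _, _ = gen_trajectory(4, 7, jitter_sd=0.3, seed=15)
        traj.elements = ["C", "N", "O", "H", "C", "S", "P"]
        path = tmp_path / "t.xyz"
        write_xyz(traj, path)
        back = read_xyz(path)
        assert back.n_frames == 4 and back.n_atoms == 7
        assert back.elements == traj.elements
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-9)

    def test_pdb_roundtrip(self, tmp_path):
        traj, _, _ = gen_trajectory(3, 5, jitter_sd=0.2, seed=16)
        traj.elements = ["C"] * 5
        path = tmp_path / "t.pdb"
        write_pdb_models(traj, path)
        back = read_pdb_models(path)
        assert back.n_frames == 3 and back.n_atoms == 5
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)  # PDB 3-decimal

    def test_empty_xyz_rejected(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("")
        with pytest.raises(ValueError):
            read_xyz(path)
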