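"""Structural observables against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from allokit.observables import (rmsd_series, rmsf_profile, count_contacts,
                                 hydrogen_bonds, radius_of_gyration, sasa,
                                 essential_dynamics, free_energy_surface,
                                 porcupine_export)
from allokit.trajectory import Trajectory, superpose
from .conftest import make_ca_trajectory


class TestRMSD:
    def test_identical_frames_zero(self, rng):
        base = rng.normal(size=(1, 6, 3))
        traj = make_ca_trajectory(np.tile(base, (5, 1, 1)))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_rigid_motions_zero(self, rng):
        from scipy.spatial.transform import Rotation
        base = rng.normal(size=(6, 3))
        frames = [base] + [base @ Rotation.random(
            random_state=rng).as_matrix().T + rng.normal(size=3)
            for _ in range(4)]
        traj = make_ca_trajectory(np.stack(frames))
        assert rmsd_series(traj).max() < 1e-6

    def test_matches_numeric_optimizer_on_toy(self, rng):
        """Kabsch-fitted RMSD equals brute-force minimization over
        rotations and translations."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        ref = rng.normal(size=(4, 3))
        mob = ref + 0.2 * rng.normal(size=(4, 3))
        traj = make_ca_trajectory(np.stack([ref, mob]))
        ours = rmsd_series(traj)[1]

        def objective(p):
            rot = Rotation.from_rotvec(p[:3]).as_matrix()
            return np.sqrt(np.mean(np.sum(
                (mob @ rot.T + p[3:] - ref) ** 2, axis=1)))

        best = min(minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 5000}).fun
                   for x0 in [np.zeros(6),
                              rng.normal(size=6) * 0.5,
                              rng.normal(size=6) * 0.5])
        assert ours == pytest.approx(best, abs=1e-6)


class TestRMSF:
    def test_static_trajectory_zero(self, rng):
        traj = make_ca_trajectory(np.tile(rng.normal(size=(1, 5, 3)),
                                          (6, 1, 1)))
        np.testing.assert_allclose(rmsf_profile(traj).rmsf, 0.0,
                                   atol=1e-12)

    def test_two_point_alternation_gives_half_distance(self):
        # one residue hopping between two points distance d apart → d/2
        d = 0.8
        frames = np.zeros((10, 3, 3))
        frames[1::2, 0, 0] = d
        frames[:, 1, 1] = 5.0  # static companions
        frames[:, 2, 2] = 9.0
        prof = rmsf_profile(make_ca_trajectory(frames))
        assert prof.rmsf[0] == pytest.approx(d / 2)
        assert prof.rmsf[1] == pytest.approx(0.0, abs=1e-12)

    def test_rmsf_squared_sums_to_covariance_trace(self, short_trajectory):
        traj = superpose(short_trajectory)
        prof = rmsf_profile(traj)
        ed = essential_dynamics(traj)
        assert np.sum(prof.rmsf ** 2) == pytest.approx(
            np.sum(ed.eigenvalues), rel=1e-8)


class TestContacts:
    @staticmethod
    def _two_atom_traj(distance):
        coords = np.array([[[0, 0, 0], [distance, 0, 0]]], dtype=float)
        meta = pd.DataFrame({
            "name": ["O", "N"], "element": ["O", "N"],
            "heavy": [True, True], "resid": [0, 1],
            "resname": ["X", "Y"], "chain": ["A", "A"]})
        return Trajectory(coords, meta, np.array([0.0]))

    def test_pair_inside_cutoff_counts(self):
        assert count_contacts(self._two_atom_traj(0.40))[0] == 1

    def test_pair_outside_cutoff_ignored(self):
        assert count_contacts(self._two_atom_traj(0.50))[0] == 0

    def test_same_residue_pair_excluded(self):
        traj = self._two_atom_traj(0.2)
        traj.atom_meta["resid"] = [0, 0]
        assert count_contacts(traj)[0] == 0

    def test_neighbor_list_equals_brute_force(self, rng):
        for _ in range(5):
            coords = rng.uniform(0, 2.0, size=(1, 100, 3))
            meta = pd.DataFrame({
                "name": ["C"] * 100, "element": ["C"] * 100,
                "heavy": [True] * 100,
                "resid": np.arange(100) // 3,
                "resname": ["X"] * 100, "chain": ["A"] * 100})
            traj = Trajectory(coords, meta, np.array([0.0]))
            d = np.linalg.norm(coords[0][:, None] - coords[0][None], axis=-1)
            resid = meta["resid"].values
            brute = sum(1 for i in range(100) for j in range(i + 1, 100)
                        if d[i, j] < 0.45 and resid[i] != resid[j])
            assert count_contacts(traj)[0] == brute


class TestHydrogenBonds:
    @staticmethod
    def _nho_traj(d_no, angle_deg):
        """N–H donor plus acceptor O with a chosen N..O distance and
        D–H–A angle."""
        nh = 0.10
        h = np.array([nh, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        acc_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
        # place acceptor so that |N-O| = d_no along the angle-defining ray
        from scipy.optimize import brentq
        f = lambda t: np.linalg.norm(h + t * acc_dir) - d_no
        t = brentq(f, 1e-4, 2.0)
        o = h + t * acc_dir
        coords = np.array([[[0, 0, 0], h, o]])
        meta = pd.DataFrame({
            "name": ["N", "H", "O"], "element": ["N", "H", "O"],
            "heavy": [True, False, True], "resid": [0, 0, 1],
            "resname": ["X", "X", "Y"], "chain": ["A"] * 3})
        return Trajectory(coords, meta, np.array([0.0]))

    def test_good_geometry_detected(self):
        bonds = hydrogen_bonds(self._nho_traj(0.30, 180.0))[0]
        assert len(bonds) == 1
        assert bonds[0].donor == 0 and bonds[0].acceptor == 2
        assert bonds[0].angle == pytest.approx(180.0, abs=1e-6)

    def test_bent_geometry_rejected(self):
        assert hydrogen_bonds(self._nho_traj(0.30, 140.0))[0] == []

    def test_long_distance_rejected(self):
        assert hydrogen_bonds(self._nho_traj(0.36, 180.0))[0] == []

    def test_angle_just_above_threshold_accepted(self):
        assert len(hydrogen_bonds(self._nho_traj(0.30, 151.0))[0]) == 1

    def test_no_hydrogens_warns_and_returns_empty(self, short_trajectory):
        with pytest.warns(UserWarning, match="no hydrogens"):
            out = hydrogen_bonds(short_trajectory)
        assert all(b == [] for b in out)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        traj = make_ca_trajectory(np.ones((2, 1, 3)))
        np.testing.assert_allclose(radius_of_gyration(traj), 0.0,
                                   atol=1e-12)

    def test_two_equal_masses_half_distance(self):
        d = 1.4
        coords = np.array([[[0, 0, 0], [d, 0, 0]]])
        traj = make_ca_trajectory(coords)
        assert radius_of_gyration(traj)[0] == pytest.approx(d / 2)

    def test_homogeneous_scaling(self, short_trajectory):
        rg1 = radius_of_gyration(short_trajectory)
        doubled = Trajectory(short_trajectory.coords * 2,
                             short_trajectory.atom_meta.copy(),
                             short_trajectory.times.copy())
        np.testing.assert_allclose(radius_of_gyration(doubled), 2 * rg1,
                                   rtol=1e-12)


class TestSASA:
    def test_isolated_sphere_analytic(self):
        r = 0.17
        per_atom, total = sasa(np.zeros((1, 3)), np.array([r]))
        exact = 4 * np.pi * (r + 0.14) ** 2
        assert abs(total - exact) / exact < 0.02

    def test_fully_buried_atom_zero(self):
        # central atom caged by 26 overlapping neighbors
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([[0.0, 0.0, 0.0],
                            0.25 * np.array(offsets)])
        radii = np.full(len(coords), 0.17)
        per_atom, _ = sasa(coords, radii)
        assert per_atom[0] == 0.0

    def test_occlusion_monotone(self):
        radii = np.full(2, 0.17)
        _, near = sasa(np.array([[0, 0, 0], [0.3, 0, 0.0]]), radii)
        _, far = sasa(np.array([[0, 0, 0], [5.0, 0, 0.0]]), radii)
        assert near < far

    def test_agrees_with_mdtraj_reference(self, rng):
        """Independent cross-check against the Shrake–Rupley
        implementation in mdtraj on a random 10-atom cluster."""
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as elem

        coords = rng.uniform(0, 0.8, size=(10, 3))
        radius_c = 0.17
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("XXX", chain)
        for i in range(10):
            top.add_atom(f"C{i}", elem.carbon, res)
        t = mdtraj.Trajectory(coords[None], top)
        ref = mdtraj.shrake_rupley(t, probe_radius=0.14,
                                   n_sphere_points=960)[0]
        mine, _ = sasa(coords, np.full(10, radius_c),
                       n_sphere_points=960)
        # mdtraj uses its own radius table for carbon (0.17 nm = ours)
        np.testing.assert_allclose(mine, ref, rtol=0.08, atol=5e-3)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([0.0]))


class TestEssentialDynamics:
    def test_eigenvalue_sum_equals_trace(self, short_trajectory):
        traj = superpose(short_trajectory)
        ed = essential_dynamics(traj)
        ca = traj.ca_coords().reshape(traj.n_frames, -1)
        cov_trace = ((ca - ca.mean(0)) ** 2).mean(0).sum()
        assert ed.eigenvalues.sum() == pytest.approx(cov_trace, rel=1e-8)

    def test_single_axis_motion_is_rank_one(self):
        frames = np.zeros((20, 4, 3))
        t = np.linspace(0, 1, 20)
        frames[:, 0, 0] = t          # only one coordinate moves
        frames[:, 1, 1] = 3.0
        frames[:, 2, 2] = 6.0
        frames[:, 3, 0] = 9.0
        ed = essential_dynamics(make_ca_trajectory(frames))
        assert ed.variance_fraction(1) == pytest.approx(1.0, abs=1e-10)

    def test_full_basis_reconstruction(self, short_trajectory):
        traj = superpose(short_trajectory)
        ed = essential_dynamics(traj)
        ca = traj.ca_coords().reshape(traj.n_frames, -1)
        centered = ca - ca.mean(0)
        np.testing.assert_allclose(ed.reconstruct(), centered, atol=1e-8)

    def test_eigenvector_orthonormality(self, short_trajectory):
        ed = essential_dynamics(superpose(short_trajectory))
        gram = ed.eigenvectors.T @ ed.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


class TestFreeEnergySurface:
    def test_uniform_occupancy_is_flat_zero(self):
        # one frame in each of 4×4 bins → P/P_max = 1 everywhere
        centers = np.linspace(0.125, 0.875, 4)
        pts = np.array([(x, y) for x in centers for y in centers])
        fel = free_energy_surface(pts, bins=4)
        np.testing.assert_allclose(fel.free_energy, 0.0, atol=1e-12)
        assert fel.counts.sum() == 16

    def test_half_occupancy_bin_is_ln2(self):
        pts = np.array([[0.1, 0.1]] * 4 + [[0.9, 0.9]] * 2)
        fel = free_energy_surface(pts, bins=2)
        assert fel.free_energy.min() == 0.0
        vals = fel.free_energy[np.isfinite(fel.free_energy)]
        assert sorted(vals) == pytest.approx([0.0, np.log(2)])

    def test_empty_bins_are_unbounded_not_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        fel = free_energy_surface(pts, bins=3)
        assert np.isinf(fel.free_energy).sum() == 7
        assert fel.counts.sum() == 2

    def test_single_basin_valid(self):
        pts = np.zeros((50, 2))
        fel = free_energy_surface(pts, bins=2)
        assert (fel.counts == 50).sum() == 1

    def test_kj_per_mol_conversion(self):
        pts = np.array([[0.1, 0.1]] * 4 + [[0.9, 0.9]] * 2)
        fel = free_energy_surface(pts, bins=2, temperature=300.0)
        kt = 0.00831446261815324 * 300.0
        finite = np.isfinite(fel.free_energy)
        np.testing.assert_allclose(fel.in_kj_per_mol()[finite],
                                   fel.free_energy[finite] * kt)


class TestPorcupine:
    def test_export_counts_and_proportionality(self, short_trajectory,
                                               tmp_path):
        ed = essential_dynamics(superpose(short_trajectory))
        out = porcupine_export(ed, 0, 2.5, tmp_path / "p.tsv")
        rows = [line.split("\t") for line
                in out.read_text().splitlines()[2:]]
        assert len(rows) == short_trajectory.n_residues
        vecs = np.array([[float(v) for v in r[1:]] for r in rows])
        loadings = np.linalg.norm(
            ed.eigenvectors[:, 0].reshape(-1, 3), axis=1)
        norms = np.linalg.norm(vecs, axis=1)
        # TSV carries 6 decimals → compare at that absolute precision
        np.testing.assert_allclose(norms, 2.5 * loadings, atol=3e-6)
        assert (tmp_path / "p.pml").exists()

    def test_zero_scale_is_valid(self, short_trajectory, tmp_path):
        ed = essential_dynamics(superpose(short_trajectory))
        out = porcupine_export(ed, 0, 0.0, tmp_path / "z.tsv")
        vecs = np.loadtxt(out, skiprows=2)[:, 1:]
        np.testing.assert_array_equal(vecs, 0.0)

    def test_component_out_of_range(self, short_trajectory, tmp_path):
        ed = essential_dynamics(superpose(short_trajectory))
        with pytest.raises(ValueError):
            porcupine_export(ed, 10_000, 1.0, tmp_path / "x.tsv")
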