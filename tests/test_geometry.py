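"""Superposition, RMSD/RMSF and PCA against closed forms and planted truth."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mutscan.geometry import (exclude_terminal_residues, kabsch_superpose,
                              pca_covariance, rmsd_series, rmsf_per_residue)
from mutscan.synthetic import (SyntheticSpec, make_toy_complex,
                               simulate_trajectory)
from mutscan.system import (SelectionMask, Trajectory, backbone_mask,
                            calpha_mask)


def _cloud(rng, n=10):
    return rng.standard_normal((n, 3)) * 3.0


class TestKabschSuperpose:
    def test_identical_structures(self, rng):
        x = _cloud(rng)
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_pure_translation_recovered(self, rng):
        x = _cloud(rng)
        res = kabsch_superpose(x + np.array([1.0, 2.0, 3.0]), x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.translation, [-1.0, -2.0, -3.0],
                                   atol=1e-10)

    def test_known_rotation_recovered(self, rng):
        x = _cloud(rng)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True)
        mobile = x @ rot.as_matrix().T
        res = kabsch_superpose(mobile, x)
        assert res.rmsd < 1e-8
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        np.testing.assert_allclose(mobile @ res.rotation + res.translation,
                                   x, atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent route: scipy's Wahba solver on centered clouds."""
        x = _cloud(rng)
        y = _cloud(rng)
        res = kabsch_superpose(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot, _ = Rotation.align_vectors(yc, xc)
        np.testing.assert_allclose(res.rotation, rot.as_matrix().T, atol=1e-8)

    def test_collinear_mask_is_degenerate(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(x, x + 1.0)

    def test_rmsd_symmetric(self, rng):
        x = _cloud(rng)
        y = x + rng.standard_normal(x.shape) * 0.5
        assert kabsch_superpose(x, y).rmsd == pytest.approx(
            kabsch_superpose(y, x).rmsd, abs=1e-10
        )


class TestRmsdSeries:
    def test_zero_noise_trajectory_all_zero(self):
        spec = SyntheticSpec(n_residues=5, fluctuation_amplitudes=0.0,
                             ligand_amplitude=0.0, replica_count=1,
                             frames_per_replica=5, seed=0)
        system = make_toy_complex(spec)
        traj, _ = simulate_trajectory(system, spec)
        series = rmsd_series(traj, system.coords,
                             fit_mask=backbone_mask(system))
        np.testing.assert_allclose(series, 0.0, atol=1e-10)

    def test_consistent_with_superposition_rmsd(self, wt_system, wt_trajectory):
        traj, _ = wt_trajectory
        mask = backbone_mask(wt_system)
        series = rmsd_series(traj, traj.coords[0], fit_mask=mask,
                             measure_mask=mask)
        for f in (1, 5, 9):
            ref = kabsch_superpose(traj.coords[f][mask.atom_indices],
                                   traj.coords[0][mask.atom_indices])
            assert series[f] == pytest.approx(ref.rmsd, abs=1e-10)

    def test_empty_measure_mask_is_error(self, wt_system, wt_trajectory):
        traj, _ = wt_trajectory
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, traj.coords[0],
                        fit_mask=backbone_mask(wt_system),
                        measure_mask=SelectionMask(np.array([], dtype=int)))

    def test_mean_matches_monte_carlo_oracle(self, rng):
        """Planted isotropic Gaussian noise: series mean agrees with an
        independent Monte-Carlo estimate built on scipy's fitting route."""
        a = 0.6
        base = _cloud(rng, n=30)
        n_frames = 400
        noise = rng.standard_normal((n_frames, 30, 3)) * (a / np.sqrt(3))
        traj = Trajectory(base + noise, frame_spacing=1.0)
        series = rmsd_series(traj, base, fit_mask=SelectionMask(np.arange(30)))

        oracle_vals = []
        for _ in range(200):
            x = base + rng.standard_normal((30, 3)) * (a / np.sqrt(3))
            xc = x - x.mean(axis=0)
            bc = base - base.mean(axis=0)
            rot, rssd = Rotation.align_vectors(bc, xc)
            oracle_vals.append(rssd / np.sqrt(30))
        se = np.std(oracle_vals) / np.sqrt(len(oracle_vals)) \
            + np.std(series) / np.sqrt(len(series))
        assert abs(series.mean() - np.mean(oracle_vals)) < 4 * se


class TestExcludeTerminalResidues:
    def test_zero_is_identity(self, wt_system):
        mask = backbone_mask(wt_system)
        out = exclude_terminal_residues(mask, wt_system, 0)
        np.testing.assert_array_equal(out.atom_indices, mask.atom_indices)

    def test_ten_residue_chain_minus_six_keeps_first_four(self):
        spec = SyntheticSpec(n_residues=10, seed=0)
        system = make_toy_complex(spec)
        mask = backbone_mask(system)
        out = exclude_terminal_residues(mask, system, 6)
        kept = set(system.res_ids[out.atom_indices])
        assert kept == {1, 2, 3, 4}

    def test_ligand_atoms_never_removed(self, wt_system):
        from mutscan.system import all_atom_mask
        out = exclude_terminal_residues(all_atom_mask(wt_system), wt_system, 3)
        lig = set(wt_system.ligand_indices())
        assert lig <= set(out.atom_indices)

    def test_whole_chain_removal_is_error(self, wt_system):
        with pytest.raises(ValueError, match="n_cterm"):
            exclude_terminal_residues(backbone_mask(wt_system), wt_system, 9)


class TestRmsfPerResidue:
    def test_zero_noise_all_zero(self):
        spec = SyntheticSpec(n_residues=5, fluctuation_amplitudes=0.0,
                             ligand_amplitude=0.0, replica_count=1,
                             frames_per_replica=4, seed=0)
        system = make_toy_complex(spec)
        traj, _ = simulate_trajectory(system, spec)
        prof = rmsf_per_residue(traj, system, backbone_mask(system))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-10)

    def test_recovers_planted_amplitude_profile(self):
        """Quiet ends, one mobile residue (0.2 / 0.8 / 0.2 Å pattern)."""
        amps = np.full(12, 0.2)
        amps[5] = 0.8
        spec = SyntheticSpec(n_residues=12, fluctuation_amplitudes=amps,
                             ligand_amplitude=0.0, replica_count=1,
                             frames_per_replica=2000, seed=21)
        system = make_toy_complex(spec)
        traj, truth = simulate_trajectory(system, spec)
        prof = rmsf_per_residue(traj, system, backbone_mask(system))
        assert prof.values[5] > prof.values[4]
        assert prof.values[5] > prof.values[6]
        # the rigid-body fit absorbs ~6/3N of the variance; allow that plus
        # estimator noise
        np.testing.assert_allclose(prof.values, amps, rtol=0.1)

    def test_doubling_amplitudes_doubles_rmsf(self):
        amps = np.array([0.2, 0.5, 0.3, 0.4])
        prof = {}
        for scale in (1.0, 2.0):
            spec = SyntheticSpec(n_residues=4,
                                 fluctuation_amplitudes=amps * scale,
                                 ligand_amplitude=0.0, replica_count=1,
                                 frames_per_replica=2000, seed=8)
            system = make_toy_complex(spec)
            traj, _ = simulate_trajectory(system, spec)
            prof[scale] = rmsf_per_residue(traj, system,
                                           backbone_mask(system)).values
        np.testing.assert_allclose(prof[2.0] / prof[1.0], 2.0, rtol=0.05)

    def test_invariant_to_rigid_motion_of_all_frames(self, wt_system,
                                                     wt_trajectory):
        traj, _ = wt_trajectory
        mask = backbone_mask(wt_system)
        base = rmsf_per_residue(traj, wt_system, mask).values
        rot = Rotation.from_euler("z", 73, degrees=True).as_matrix()
        moved = Trajectory(traj.coords @ rot.T + np.array([5.0, -3.0, 2.0]),
                           frame_spacing=traj.frame_spacing)
        shifted = rmsf_per_residue(moved, wt_system, mask).values
        np.testing.assert_allclose(shifted, base, atol=1e-8)

    def test_single_frame_is_error(self, wt_system, wt_trajectory):
        traj, _ = wt_trajectory
        single = Trajectory(traj.coords[:1], frame_spacing=1.0)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_per_residue(single, wt_system, backbone_mask(wt_system))


class TestPcaCovariance:
    def test_zero_noise_all_eigenvalues_zero(self):
        spec = SyntheticSpec(n_residues=5, fluctuation_amplitudes=0.0,
                             ligand_amplitude=0.0, replica_count=1,
                             frames_per_replica=6, seed=0)
        system = make_toy_complex(spec)
        traj, _ = simulate_trajectory(system, spec)
        evals, _ = pca_covariance(traj, calpha_mask(system))
        np.testing.assert_allclose(evals, 0.0, atol=1e-12)

    def test_single_planted_direction_dominates(self, rng, wt_system):
        """Noise along one collective direction: top mode carries >95%."""
        mask = calpha_mask(wt_system)
        n = len(mask.atom_indices)
        direction = rng.standard_normal((n, 3))
        direction /= np.linalg.norm(direction)
        amp = rng.standard_normal(300)[:, None, None]
        coords = np.repeat(wt_system.coords[None], 300, axis=0)
        coords[:, mask.atom_indices, :] += amp * direction
        # small isotropic jitter so the covariance is full-rank-ish
        coords += rng.standard_normal(coords.shape) * 0.01
        traj = Trajectory(coords, frame_spacing=1.0)
        evals, _ = pca_covariance(traj, mask)
        assert evals[0] / evals.sum() > 0.95

    def test_eigenvalue_sum_equals_total_variance(self, wt_system,
                                                  wt_trajectory):
        traj, _ = wt_trajectory
        mask = calpha_mask(wt_system)
        evals, _ = pca_covariance(traj, mask)
        from mutscan.geometry import _average_structure
        fitted, ref = _average_structure(traj.coords, mask)
        x = (fitted[:, mask.atom_indices, :] - ref[mask.atom_indices]
             ).reshape(traj.n_frames, -1)
        total_var = np.mean(np.sum(x ** 2, axis=1))
        assert evals.sum() == pytest.approx(total_var, rel=1e-8)

    def test_too_many_modes_is_error(self, wt_system, wt_trajectory):
        traj, _ = wt_trajectory
        mask = calpha_mask(wt_system)
        with pytest.raises(ValueError, match="modes"):
            pca_covariance(traj, mask, n_modes=3 * len(mask) + 1)
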