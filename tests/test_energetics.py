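"""MM terms vs brute force, PB vs Born, SASA vs closed forms, decomposition."""

import numpy as np
import pytest

from mutscan.energetics import (COULOMB_K, EnergyBreakdown, NonpolarParams,
                                PBGridSpec, binding_energy_frame,
                                binding_energy_trajectory, born_ion_energy,
                                component_total_correlation, coulomb_interaction,
                                delta_delta_map, lj_interaction,
                                per_residue_decomposition, sasa, solve_pb)
from mutscan.synthetic import (SyntheticSpec, make_toy_complex,
                               pocket_residues, simulate_trajectory,
                               variant_charge_plans)
from mutscan.system import Trajectory

FAST_GRID = PBGridSpec(spacing=1.0, padding=8.0, ionic_strength=0.0)


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_interaction(
            np.array([[0.0, 0, 0]]), [1.0], np.array([[1.0, 0, 0]]), [-1.0]
        )
        assert e == pytest.approx(-332.0636)

    def test_zero_charge_group_gives_zero(self, rng):
        a = rng.standard_normal((4, 3))
        b = rng.standard_normal((3, 3)) + 10.0
        assert coulomb_interaction(a, [1, -1, 0.5, 2], b, [0, 0, 0]) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        a = rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 3)) + 5.0
        qa = rng.uniform(-1, 1, 5)
        qb = rng.uniform(-1, 1, 5)
        expected = 0.0
        for i in range(5):
            for j in range(5):
                expected += COULOMB_K * qa[i] * qb[j] / np.linalg.norm(
                    a[i] - b[j]
                )
        assert coulomb_interaction(a, qa, b, qb) == pytest.approx(
            expected, abs=1e-10
        )

    def test_coincident_atoms_is_error(self):
        with pytest.raises(ValueError, match="zero distance"):
            coulomb_interaction(np.zeros((1, 3)), [1.0],
                                np.zeros((1, 3)), [1.0])


class TestLennardJones:
    def test_minimum_at_combined_rmin(self):
        # rmin_ij = 1.9 + 2.1; energy at the minimum is -eps_ij
        e = lj_interaction(np.array([[0.0, 0, 0]]), [0.2], [1.9],
                           np.array([[4.0, 0, 0]]), [0.05], [2.1])
        assert e == pytest.approx(-np.sqrt(0.2 * 0.05))

    def test_vanishes_at_long_range(self):
        e = lj_interaction(np.array([[0.0, 0, 0]]), [0.2], [1.9],
                           np.array([[500.0, 0, 0]]), [0.2], [1.9])
        assert abs(e) < 1e-12

    def test_matches_double_loop_oracle(self, rng):
        a = rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 3)) + 6.0
        ea = rng.uniform(0.05, 0.3, 5)
        eb = rng.uniform(0.05, 0.3, 5)
        ra = rng.uniform(1.5, 2.2, 5)
        rb = rng.uniform(1.5, 2.2, 5)
        expected = 0.0
        for i in range(5):
            for j in range(5):
                r = np.linalg.norm(a[i] - b[j])
                eps = np.sqrt(ea[i] * eb[j])
                rmin = ra[i] + rb[j]
                expected += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert lj_interaction(a, ea, ra, b, eb, rb) == pytest.approx(
            expected, abs=1e-10
        )


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        total, per_atom = sasa(np.zeros((1, 3)), np.array([1.7]),
                               probe_radius=1.4, n_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.02)
        assert per_atom[0] == total

    def test_fully_buried_atom_is_zero(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0.1]])
        radii = np.array([1.0, 8.0])
        _, per_atom = sasa(coords, radii, probe_radius=1.4, n_points=400)
        assert per_atom[0] == 0.0

    def test_two_sphere_overlap_matches_analytic_caps(self):
        """Two intersecting spheres: exact area via spherical-cap formula."""
        r1, r2, probe, d = 1.7, 1.5, 1.4, 2.0
        R1, R2 = r1 + probe, r2 + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        # cap height on sphere 1 cut by sphere 2
        h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
        h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
        exact1 = 4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1
        exact2 = 4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2
        _, per_atom = sasa(coords, np.array([r1, r2]), probe, n_points=4000)
        assert per_atom[0] == pytest.approx(exact1, rel=0.01)
        assert per_atom[1] == pytest.approx(exact2, rel=0.01)

    def test_matches_independent_mdtraj_implementation(self, rng):
        """Cross-check on a carbon cloud (mdtraj uses element radii, so the
        fixture sticks to C with the matching 1.7 Å radius)."""
        mdtraj = pytest.importorskip("mdtraj")
        coords = rng.standard_normal((6, 3)) * 2.0
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(6):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                   n_sphere_points=960)[0] * 100.0  # Å²
        _, per_atom = sasa(coords, np.full(6, 1.7), probe_radius=1.4,
                           n_points=960)
        np.testing.assert_allclose(per_atom, ref, rtol=0.05, atol=0.5)

    def test_per_atom_sums_to_total(self, wt_system):
        total, per_atom = sasa(wt_system.coords, wt_system.pb_radius,
                               n_points=100)
        assert per_atom.sum() == pytest.approx(total)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError, match="n_points"):
            sasa(np.zeros((1, 3)), np.array([1.5]), n_points=10)


class TestPoissonBoltzmann:
    def test_born_ion_within_5pct(self):
        grid = PBGridSpec(spacing=0.4, padding=10.0, ionic_strength=0.0)
        e, per_atom = solve_pb(np.zeros((1, 3)), np.array([1.0]),
                               np.array([2.0]), grid)
        born = born_ion_energy(1.0, 2.0, grid)
        assert abs(e - born) / abs(born) < 0.05
        assert per_atom.sum() == pytest.approx(e)

    def test_grid_refinement_converges_monotonically(self):
        born = born_ion_energy(1.0, 2.0, PBGridSpec())
        errs = []
        for h in (0.8, 0.6, 0.4):
            grid = PBGridSpec(spacing=h, padding=10.0, ionic_strength=0.0)
            e, _ = solve_pb(np.zeros((1, 3)), np.array([1.0]),
                            np.array([2.0]), grid)
            errs.append(abs(e - born))
        assert errs[0] > errs[1] > errs[2]

    def test_zero_charge_solute_is_zero(self):
        grid = PBGridSpec(spacing=0.8, padding=8.0, ionic_strength=0.0)
        e, _ = solve_pb(np.zeros((1, 3)), np.array([0.0]),
                        np.array([2.0]), grid)
        assert abs(e) < 1e-6

    def test_salt_strengthens_screening(self):
        coords = np.zeros((1, 3))
        e0, _ = solve_pb(coords, np.array([1.0]), np.array([2.0]),
                         PBGridSpec(spacing=0.8, padding=8.0,
                                    ionic_strength=0.0))
        e1, _ = solve_pb(coords, np.array([1.0]), np.array([2.0]),
                         PBGridSpec(spacing=0.8, padding=8.0,
                                    ionic_strength=0.15))
        assert e1 < e0  # more favourable solvation with mobile ions

    def test_grid_too_small_is_error(self):
        grid = PBGridSpec(spacing=1.0, padding=1.0)
        with pytest.raises(ValueError, match="grid too small"):
            solve_pb(np.zeros((1, 3)), np.array([1.0]), np.array([3.0]),
                     grid)


class TestBindingEnergyFrame:
    def test_components_sum_to_total(self, wt_system):
        b = binding_energy_frame(wt_system.coords, wt_system, FAST_GRID)
        assert b.g_bind == pytest.approx(
            b.e_vdw + b.e_elect + b.g_polar + b.g_nonpolar + b.e_int
        )
        assert b.e_int == 0.0
        assert b.entropy_term is None

    def test_separated_ligand_gives_near_zero_binding(self):
        spec = SyntheticSpec(n_residues=6, charge_plan=[0] * 6, seed=0)
        system = make_toy_complex(spec)
        coords = system.coords.copy()
        lig = system.ligand_indices()
        coords[lig] += np.array([60.0, 0.0, 0.0])
        grid = PBGridSpec(spacing=1.5, padding=6.0, ionic_strength=0.0)
        b = binding_energy_frame(coords, system, grid)
        assert b.e_elect == 0.0  # neutral receptor carries no charges
        assert abs(b.e_vdw) < 1e-4  # r^-6 tail at 60 Å separation
        assert abs(b.g_bind) < 0.5  # within grid-solver tolerance

    def test_dominant_charge_pair_matches_closed_form(self, wt_system):
        """The only charges are ligand N1 (+1) and pocket OD1 (-1)."""
        b = binding_energy_frame(wt_system.coords, wt_system, FAST_GRID)
        charged = np.flatnonzero(wt_system.charges != 0)
        assert len(charged) == 2
        r = np.linalg.norm(np.diff(wt_system.coords[charged], axis=0))
        assert b.e_elect == pytest.approx(-COULOMB_K / r, rel=1e-6)

    def test_unparameterized_atoms_is_error(self, wt_system):
        broken = wt_system.subset(np.arange(wt_system.n_atoms))
        broken.charges[0] = np.nan
        with pytest.raises(ValueError, match="unset"):
            binding_energy_frame(broken.coords, broken, FAST_GRID)


class TestBindingEnergyTrajectory:
    def test_single_frame_equals_frame_result(self, wt_system):
        traj = Trajectory(wt_system.coords[None], frame_spacing=1.0)
        one = binding_energy_trajectory(traj, wt_system, FAST_GRID)
        ref = binding_energy_frame(wt_system.coords, wt_system, FAST_GRID)
        assert one.g_bind == pytest.approx(ref.g_bind)
        assert one.g_bind_std == 0.0

    def test_mean_components_sum_to_mean_total(self, wt_system,
                                               wt_trajectory):
        traj, _ = wt_trajectory
        rep = binding_energy_trajectory(traj, wt_system, FAST_GRID,
                                        stride=10, include_pb=False)
        assert rep.g_bind == pytest.approx(
            rep.e_vdw + rep.e_elect + rep.g_polar + rep.g_nonpolar
        )
        df = rep.per_frame
        assert np.allclose(
            df.g_bind,
            df.e_vdw + df.e_elect + df.g_polar + df.g_nonpolar,
        )

    def test_report_assembled_from_printed_components(self):
        rep = EnergyBreakdown.from_components(-64.0, -106.0, 76.0)
        assert rep.g_bind == pytest.approx(-94.0)


class TestPerResidueDecomposition:
    def test_contributions_sum_to_total(self, wt_system, wt_trajectory):
        traj, _ = wt_trajectory
        dec = per_residue_decomposition(traj, wt_system, FAST_GRID, stride=20)
        rep = binding_energy_trajectory(traj, wt_system, FAST_GRID, stride=20)
        assert dec.total.sum() == pytest.approx(rep.g_bind, abs=1e-6)

    def test_mm_terms_conserved_to_1e6(self, wt_system, wt_trajectory):
        traj, _ = wt_trajectory
        dec = per_residue_decomposition(traj, wt_system, FAST_GRID,
                                        stride=10, include_pb=False)
        rep = binding_energy_trajectory(traj, wt_system, FAST_GRID,
                                        stride=10, include_pb=False)
        assert abs(dec.components["elect"].sum() - rep.e_elect) < 1e-6
        assert abs(dec.components["vdw"].sum() - rep.e_vdw) < 1e-6

    def test_far_neutral_residue_contributes_nothing(self, wt_system):
        traj = Trajectory(wt_system.coords[None], frame_spacing=1.0)
        dec = per_residue_decomposition(traj, wt_system, FAST_GRID,
                                        include_pb=False)
        # residue 1 is neutral and ~12 Å from the ligand
        assert abs(dec.total[0]) < 0.3

    def test_planted_asp_dominates_electrostatics(self, wt_system):
        traj = Trajectory(wt_system.coords[None], frame_spacing=1.0)
        dec = per_residue_decomposition(traj, wt_system, FAST_GRID,
                                        include_pb=False)
        elect = dec.components["elect"]
        receptor_rows = [i for i, r in enumerate(dec.residues)
                         if r[0] == "A"]
        asp_row = [i for i in receptor_rows
                   if dec.residues[i][2] == "ASP"][0]
        rec_total = sum(elect[i] for i in receptor_rows)
        assert elect[asp_row] / rec_total > 0.9


class TestDeltaDeltaMap:
    def _decompositions(self):
        plans = variant_charge_plans(9)
        out = {}
        for label in ("wildtype", "resistant"):
            spec = SyntheticSpec(n_residues=9, charge_plan=plans[label],
                                 seed=0)
            system = make_toy_complex(spec)
            traj = Trajectory(system.coords[None], frame_spacing=1.0)
            out[label] = per_residue_decomposition(
                traj, system, FAST_GRID, include_pb=False
            )
        return out

    def test_identical_systems_give_zero(self):
        dec = self._decompositions()["wildtype"]
        ddg = delta_delta_map(dec, dec)
        np.testing.assert_allclose(ddg.ddg, 0.0, atol=1e-12)
        assert not ddg.flagged.any()

    def test_antisymmetric_under_swap(self):
        d = self._decompositions()
        fwd = delta_delta_map(d["resistant"], d["wildtype"])
        rev = delta_delta_map(d["wildtype"], d["resistant"])
        np.testing.assert_allclose(fwd.ddg, -rev.ddg, atol=1e-12)

    def test_charge_removal_localizes_to_mutated_and_ligand_residues(self):
        """Neutralizing the pocket Asp moves only that residue's share and
        the ligand's paired half; every other receptor residue is unmoved."""
        d = self._decompositions()
        ddg = delta_delta_map(d["resistant"], d["wildtype"])
        p1, _ = pocket_residues(SyntheticSpec(n_residues=9))
        for i, (chain, rid, _name) in enumerate(ddg.residues):
            if chain == "A" and rid != p1:
                assert abs(ddg.ddg[i]) < 1e-9
        mutated = [i for i, r in enumerate(ddg.residues)
                   if r[0] == "A" and r[1] == p1][0]
        assert ddg.ddg[mutated] > 1.0
        assert ddg.flagged[mutated]


class TestComponentTotalCorrelation:
    def test_component_identical_to_total_gives_one(self):
        reports = [EnergyBreakdown(0.0, e, 0.0, 0.0) for e in (-5, -2, -9.0)]
        assert component_total_correlation(reports, "e_elect") \
            == pytest.approx(1.0)

    def test_independent_component_gives_near_zero(self, rng):
        # construct totals independent of the vdw component: e_vdw = x,
        # e_elect = y - x, so g_bind = y with (x, y) independent draws
        n = 500
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        null = [EnergyBreakdown(xi, yi - xi, 0.0, 0.0)
                for xi, yi in zip(x, y)]
        assert abs(component_total_correlation(null, "e_vdw")) \
            < 3 / np.sqrt(n)

    def test_published_table_pairs_match_hand_computed_pearson(self):
        """Six (electrostatic, total) pairs; independent hand computation
        of Pearson r gives 0.98857."""
        elect = [-76.0, -54.0, -75.0, -56.0, -106.0, -67.0]
        bind = [-69.0, -42.0, -61.0, -43.0, -94.0, -51.0]
        reports = [
            EnergyBreakdown(e_vdw=b - e, e_elect=e, g_polar=0.0,
                            g_nonpolar=0.0)
            for e, b in zip(elect, bind)
        ]
        assert component_total_correlation(reports, "e_elect") \
            == pytest.approx(0.98857, abs=1e-4)

    def test_too_few_or_degenerate_reports_are_errors(self):
        reports = [EnergyBreakdown(0.0, -5.0, 0.0, 0.0)] * 2
        with pytest.raises(ValueError, match="3 reports"):
            component_total_correlation(reports, "e_elect")
        flat = [EnergyBreakdown(0.0, -5.0, 0.0, 0.0)] * 4
        with pytest.raises(ValueError, match="variance"):
            component_total_correlation(flat, "e_elect")
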