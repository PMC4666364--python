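"""Voxel grid, occupancy/orientation bookkeeping, energies, entropies."""

import math

import numpy as np
import pytest

from gistlab.constants import KB_KCAL
from gistlab.gist import (
    BulkReference,
    OMEGA_SO3,
    accumulate_voxel_stats,
    build_grid,
    geodesic_ball_volume,
    grid_around,
    nn_orientational_entropy,
    orient_entropy_map,
    quaternion_nn_distances,
    relative_orientational_entropy,
    trans_entropy_map,
    voxel_energies,
    water_orientations,
)
from gistlab.synthetic import (
    gen_orientation_samples,
    gen_uniform_solvent_frames,
    oracle_direct,
    water_site_coords,
)

from conftest import build_water_trajectory

KBT298 = KB_KCAL * 298.0


class TestGrid:
    def test_dims_and_volume(self):
        g = build_grid((0, 0, 0), (10, 10, 10), 0.5)
        assert g.dims == (20, 20, 20)
        assert g.n_voxels == 8000
        assert g.voxel_volume == pytest.approx(0.125)

    def test_margin_covers_solute(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 5.0, 2.0]])
        g = grid_around(coords, margin=7.0, spacing=0.5)
        extent = np.array(g.dims) * g.spacing
        assert np.all(extent >= (np.ptp(coords, axis=0) + 14.0) - 1e-9)

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 0), (1, 1, 1), 0.0)

    def test_boundary_point_goes_to_upper_voxel(self):
        g = build_grid((0, 0, 0), (2, 2, 2), 1.0)
        idx = g.voxel_indices(np.array([[1.0, 0.5, 0.5]]))
        assert idx[0] == np.ravel_multi_index((1, 0, 0), g.dims)
        # never double-counted: a single point maps to exactly one voxel
        assert g.voxel_indices(np.array([[2.0, 0.5, 0.5]]))[0] == -1  # outside


class TestOccupancy:
    def test_immobile_water_closed_form(self):
        g = build_grid((0, 0, 0), (4, 4, 4), 0.5)
        center = np.array([[1.25, 1.25, 1.25]])
        traj = build_water_trajectory([center] * 10)
        vm = accumulate_voxel_stats(traj, g, BulkReference())
        k = g.voxel_indices(center)[0]
        assert vm.n[k] == pytest.approx(1.0)
        assert vm.g[k] == pytest.approx(1.0 / (0.0329 * 0.125), rel=1e-12)
        others = np.delete(vm.n, k)
        assert np.all(others == 0)

    def test_count_conservation(self):
        traj = gen_uniform_solvent_frames(
            0.0329, (15, 15, 15), 40, seed=2, water_params="zero"
        )
        g = build_grid((2, 2, 2), (13, 13, 13), 0.5)  # interior subgrid
        vm = accumulate_voxel_stats(traj, g, BulkReference())
        total = 0
        trip = traj.topology.water_triplets()
        for f in traj:
            o = f.coordinates[trip[:, 0]][f.active_mask()[trip[:, 0]]]
            inside = np.all((o >= 2.0) & (o < 13.0), axis=1)
            total += inside.sum()
        assert vm.n.sum() * traj.frame_count == pytest.approx(total)

    def test_eq1_identity_everywhere(self):
        traj = gen_uniform_solvent_frames(
            0.05, (10, 10, 10), 5, seed=3, water_params="zero"
        )
        g = build_grid((0, 0, 0), (10, 10, 10), 1.0)
        bulk = BulkReference()
        vm = accumulate_voxel_stats(traj, g, bulk)
        np.testing.assert_allclose(vm.g, vm.n / (bulk.rho0 * g.voxel_volume))

    def test_orientation_convention_roundtrip(self):
        """Waters placed with quaternion q are read back as q (antipodal-aware)."""
        rng = np.random.default_rng(4)
        q = gen_orientation_samples(50, kappa=0.0, seed=rng)
        o = rng.uniform(1, 9, size=(50, 3))
        sites = water_site_coords(o, q)
        q2 = water_orientations(sites[:, 0], sites[:, 1], sites[:, 2])
        dots = np.abs(np.sum(q * q2, axis=1))
        np.testing.assert_allclose(dots, 1.0, atol=1e-9)


class TestEnergies:
    def test_two_point_charges_half_attribution(self):
        # waters whose hydrogens carry no charge: pair energy is O-O Coulomb
        g = build_grid((0, 0, 0), (8, 8, 8), 0.5)
        o = np.array([[2.1, 2.1, 2.1], [4.1, 2.1, 2.1]])  # 2 Å apart
        traj = build_water_trajectory([o], water_params="zero")
        traj.topology.charges[traj.topology.elements == "O"] = [1.0, -1.0]
        vm = voxel_energies(traj, g)
        k1, k2 = g.voxel_indices(o)
        assert vm.E_ww.sum() == pytest.approx(-332.0637 / 2.0, rel=1e-10)
        assert vm.E_ww[k1] == pytest.approx(-83.016, rel=1e-4)
        assert vm.E_ww[k2] == pytest.approx(-83.016, rel=1e-4)

    def test_lj_zero_at_sigma(self):
        g = build_grid((0, 0, 0), (8, 8, 8), 0.5)
        o = np.array([[2.0, 2.0, 2.0], [5.0, 2.0, 2.0]])
        traj = build_water_trajectory([o], water_params="zero")
        top = traj.topology
        ox = top.elements == "O"
        top.lj_sigma[ox] = 3.0  # equals the O-O distance
        top.lj_epsilon[ox] = 0.5
        vm = voxel_energies(traj, g)
        assert vm.E_ww.sum() == pytest.approx(0.0, abs=1e-12)

    def test_closure_against_oracle(self):
        """Voxel sums reproduce O(N²) totals on a charged 30-water frame."""
        from gistlab.synthetic import ShellModelSpec, gen_shell_solvent_frames

        spec = ShellModelSpec(
            solute_kind="sphere",
            solute_charge=-1.0,
            box=(10.0, 10.0, 10.0),
            g_shells=[(0.0, 2.0, 0.0)],
            g_outside=1.0,
            n_frames=2,
            seed=8,
            water_params="tip3p",
        )
        traj, info = gen_shell_solvent_frames(spec)
        grid = info["grid"]
        vm = voxel_energies(traj, grid)
        orc = oracle_direct(traj, grid)
        assert vm.E_ww.sum() == pytest.approx(orc.e_ww_total, rel=1e-8)
        assert vm.E_sw.sum() == pytest.approx(orc.e_sw_total, rel=1e-8)
        np.testing.assert_allclose(vm.n, orc.occupancy)

    def test_minimum_image_used_when_box_present(self):
        g = build_grid((0, 0, 0), (10, 10, 10), 0.5)
        o = np.array([[0.6, 5.0, 5.0], [9.4, 5.0, 5.0]])  # 1.2 Å via image
        traj = build_water_trajectory([o], box=np.array([10.0, 10.0, 10.0]),
                                      water_params="zero")
        traj.topology.charges[traj.topology.elements == "O"] = [1.0, 1.0]
        vm = voxel_energies(traj, g)
        assert vm.E_ww.sum() == pytest.approx(332.0637 / 1.2, rel=1e-10)

    def test_unset_parameters_rejected(self, single_water_pdb):
        from gistlab.model_io import load_structure
        from gistlab.errors import MissingParameterError

        _, traj = load_structure(single_water_pdb)
        g = build_grid((0, 0, 0), (10, 10, 10), 1.0)
        with pytest.raises(MissingParameterError):
            voxel_energies(traj, g)


class TestTranslationalEntropy:
    def test_zero_for_bulk_density(self):
        g = build_grid((0, 0, 0), (4, 4, 4), 1.0)
        traj = build_water_trajectory([[[2.0, 2.0, 2.0]]], water_params="zero")
        bulk = BulkReference()
        vm = accumulate_voxel_stats(traj, g, bulk)
        vm.g = np.ones_like(vm.g)  # constructed: g = 1 everywhere
        vm.n = bulk.rho0 * g.voxel_volume * np.ones_like(vm.n)
        vm = trans_entropy_map(vm, bulk)
        np.testing.assert_allclose(vm.TdS_tr, 0.0, atol=1e-15)

    def test_per_water_value_at_g2(self):
        g = build_grid((0, 0, 0), (2, 2, 2), 1.0)
        bulk = BulkReference()
        from gistlab.gist import VoxelMap

        n = 2.0 * bulk.rho0 * g.voxel_volume * np.ones(g.n_voxels)
        vm = VoxelMap(grid=g, n_frames=1, n=n, g=2.0 * np.ones(g.n_voxels))
        vm = trans_entropy_map(vm, bulk)
        per_water = vm.TdS_tr / n
        assert per_water[0] == pytest.approx(-KBT298 * math.log(2), rel=1e-6)
        assert per_water[0] == pytest.approx(-0.4105, abs=2e-4)


class TestOrientationalEntropy:
    def test_uniform_near_zero(self):
        q = gen_orientation_samples(10_000, kappa=0.0, seed=21)
        tds = KBT298 * relative_orientational_entropy(q)
        assert abs(tds) < 0.05

    def test_ball_closed_form(self):
        r = 0.1
        q = gen_orientation_samples(10_000, ball_radius=r, seed=22)
        expected = math.log(geodesic_ball_volume(r) / OMEGA_SO3)
        est = relative_orientational_entropy(q)
        assert est == pytest.approx(expected, rel=0.05)
        assert KBT298 * expected == pytest.approx(-5.83, abs=0.01)

    def test_identical_orientations_finite(self):
        q = np.tile([0.0, 0.0, 0.0, 1.0], (50, 1))
        h = nn_orientational_entropy(q)
        assert np.isfinite(h)
        tds = KBT298 * (h - math.log(OMEGA_SO3))
        assert tds < -3.0  # strongly negative via the distance floor

    def test_antipodal_distance_zero(self):
        q = np.array([[0.0, 0.0, 0.0, 1.0], [0.0, 0.0, 0.0, -1.0]])
        d = quaternion_nn_distances(q)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_sparse_voxels_flagged(self):
        g = build_grid((0, 0, 0), (4, 4, 4), 1.0)
        traj = build_water_trajectory(
            [[[2.5, 2.5, 2.5]]] * 3, water_params="zero"
        )
        bulk = BulkReference()
        vm = accumulate_voxel_stats(traj, g, bulk)
        vm = orient_entropy_map(vm, bulk, min_samples=10)
        k = g.voxel_indices(np.array([[2.5, 2.5, 2.5]]))[0]
        assert k in vm.sparse_orientation_voxels
        assert vm.TdS_or[k] == 0.0

    def test_concentration_monotonicity(self):
        vals = []
        for kappa in (0.0, 3.0, 10.0):
            q = gen_orientation_samples(3000, kappa=kappa, seed=31)
            vals.append(
                KBT298 * min(0.0, relative_orientational_entropy(q))
            )
        assert vals[0] > vals[1] > vals[2]
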