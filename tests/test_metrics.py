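"""Shell surfaces, electrostatic potentials, SASA, H-bonds, formal charge."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gistlab.errors import GeometryError
from gistlab.metrics import (
    atom_surface_distance_distribution,
    build_shell_surface,
    count_hbonds,
    formal_net_charge,
    rsasa_scan,
    sasa,
    shell_potential_profile,
)
from gistlab.synthetic import make_toy_system, mc_sasa


class TestShellSurface:
    def test_single_atom_full_sphere(self):
        s = build_shell_surface(np.zeros((1, 3)), 5.0, points_per_atom=128)
        assert s.points.shape[0] == 128
        np.testing.assert_allclose(
            np.linalg.norm(s.points, axis=1), 5.0, rtol=1e-12
        )

    def test_two_atoms_union_removes_buried(self):
        atoms = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        s = build_shell_surface(atoms, 5.0, points_per_atom=256)
        assert s.points.shape[0] < 512
        dmin = np.min(
            np.linalg.norm(s.points[:, None, :] - atoms[None, :, :], axis=2), axis=1
        )
        assert np.max(np.abs(dmin - 5.0)) <= s.tolerance + 1e-9

    def test_degenerate_geometry_fails_loud(self):
        from gistlab.errors import SurfaceError

        with pytest.raises((SurfaceError, ValueError)):
            build_shell_surface(np.zeros((1, 3)), -1.0)


class TestShellPotential:
    def test_single_charge_exact(self):
        top, frame = make_toy_system("sphere", charge=-1.0)
        for res in (64, 256):
            p = shell_potential_profile(top, frame, [5.0], points_per_atom=res)
            assert p.potential[0] == pytest.approx(-0.2, rel=1e-12)

    def test_dipole_decays_faster_than_monopole(self):
        from gistlab.model_io import Atom, Frame, Topology

        atoms = [
            Atom(0, "A", "C", "TOY", 1, 0, charge=1.0, lj_sigma=0, lj_epsilon=0, mass=12),
            Atom(1, "B", "C", "TOY", 1, 0, charge=-1.0, lj_sigma=0, lj_epsilon=0, mass=12),
        ]
        top = Topology(atoms)
        frame = Frame(np.array([[0.0, 0.0, 0.5], [0.0, 0.0, -0.5]]))
        p = shell_potential_profile(top, frame, [6.0, 12.0], points_per_atom=512)
        ratio = abs(p.potential[1]) / abs(p.potential[0])
        assert ratio < 0.5  # monopole would give exactly 0.5

    def test_neutral_set_vanishes_far_away(self):
        top, frame = make_toy_system("dinucleotide")
        # make the toy exactly neutral for this check
        top.charges -= top.charges.sum() / top.n_atoms
        p = shell_potential_profile(top, frame, [3.0, 30.0], points_per_atom=128)
        assert abs(p.potential[1]) < abs(p.potential[0]) / 10


class TestSurfaceDistances:
    def test_single_atom_all_mass_at_rmin(self):
        s = build_shell_surface(np.zeros((1, 3)), 2.0, points_per_atom=64)
        counts, edges, dmax = atom_surface_distance_distribution(
            np.zeros((1, 3)), s, bin_width=0.5
        )
        assert dmax == pytest.approx(2.0)
        # all mass sits at 2.0 Å (split across the adjacent bins only by
        # floating-point rounding of exact distances)
        near = (edges[:-1] > 2.0 - 0.5 - 1e-9) & (edges[:-1] < 2.0 + 0.5 - 1e-9)
        assert counts[near].sum() == pytest.approx(1.0)
        assert counts[~near].sum() == pytest.approx(0.0)

    def test_duplicate_atom_same_support(self):
        atoms = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        s = build_shell_surface(atoms, 2.0, points_per_atom=128)
        _, _, dmax1 = atom_surface_distance_distribution(atoms, s)
        dup = np.vstack([atoms, atoms[:1]])
        _, _, dmax2 = atom_surface_distance_distribution(dup, s)
        assert dmax1 == pytest.approx(dmax2)

    def test_rod_envelope_exceeds_globule(self):
        """Same atom count: an elongated solute has the longer envelope."""
        rod_top, rod_frame = make_toy_system("rod", length=39.0)  # 27 atoms
        n = rod_frame.coordinates.shape[0]
        side = round(n ** (1 / 3))
        grid_pts = np.array(
            [[i, j, k] for i in range(side) for j in range(side) for k in range(side)],
            dtype=float,
        ) * 2.0
        s_rod = build_shell_surface(rod_frame.coordinates, 2.0, points_per_atom=64)
        s_glob = build_shell_surface(grid_pts, 2.0, points_per_atom=64)
        _, _, dmax_rod = atom_surface_distance_distribution(
            rod_frame.coordinates, s_rod
        )
        _, _, dmax_glob = atom_surface_distance_distribution(grid_pts, s_glob)
        assert dmax_glob < dmax_rod


class TestSasa:
    def test_isolated_atom_closed_form(self):
        area = sasa(np.zeros((1, 3)), [1.6], probe_radius=1.4)
        assert area == pytest.approx(4 * math.pi * 3.0**2, rel=1e-12)

    def test_coincident_atoms_single_sphere(self):
        area = sasa(np.zeros((2, 3)), [1.6, 1.6], probe_radius=1.4)
        assert area == pytest.approx(4 * math.pi * 3.0**2, rel=1e-12)

    def test_dumbbell_matches_mc_oracle(self):
        atoms = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.6, 1.6])
        det = sasa(atoms, radii, probe_radius=1.4, n_sphere_points=960)
        mc = mc_sasa(atoms, radii, probe_radius=1.4, n_samples_per_atom=40000, seed=3)
        assert det == pytest.approx(mc, rel=0.02)

    def test_per_atom_area_monotone_under_deletion(self):
        """Removing an occluder can only expose the remaining atoms."""
        rng = np.random.default_rng(9)
        atoms = rng.uniform(0, 6, size=(8, 3))
        radii = np.full(8, 1.6)
        full = sasa(atoms, radii, 1.4, per_atom=True)
        for drop in range(8):
            keep = np.delete(np.arange(8), drop)
            after = sasa(atoms[keep], radii[keep], 1.4, per_atom=True)
            assert np.all(after >= full[keep] - 1e-9)


class TestRsasa:
    def test_identity_at_reference(self):
        scan = rsasa_scan(np.zeros((1, 3)), [1.6], [1.4, 2.8], r0=1.4)
        assert scan.r_sasa[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_sphere_closed_form(self):
        scan = rsasa_scan(np.zeros((1, 3)), [1.6], [2.8], r0=1.4)
        assert scan.r_sasa[0] == pytest.approx((4.4 / 3.0) ** 2, rel=1e-12)

    def test_closed_form_every_probe(self):
        probes = [0.8, 1.4, 2.0, 2.8, 3.5]
        scan = rsasa_scan(np.zeros((1, 3)), [1.6], probes, r0=1.4)
        expected = [((1.6 + p) / 3.0) ** 2 for p in probes]
        np.testing.assert_allclose(scan.r_sasa, expected, rtol=5e-3)

    def test_pocketed_cage_decreases_convex_increases(self):
        """Pockets narrower than larger probes drive R_SASA down while a
        convex solute's R_SASA grows with probe size."""
        # icosahedral cage: the 1.4 Å reference probe reaches the pocketed
        # inner surface, larger probes progressively cannot
        phi = (1 + math.sqrt(5)) / 2
        verts = np.array(
            [
                [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
            ],
            dtype=float,
        )
        verts *= 6.0 / np.linalg.norm(verts[0])
        r = np.full(12, 1.6)
        scan_cage = rsasa_scan(verts, r, [2.0, 2.8], r0=1.4)
        scan_convex = rsasa_scan(np.zeros((1, 3)), [1.6], [2.0, 2.8], r0=1.4)
        assert scan_cage.r_sasa[1] < scan_cage.r_sasa[0] < 1.0
        assert 1.0 < scan_convex.r_sasa[0] < scan_convex.r_sasa[1]


class TestHBonds:
    def _water_at(self, o, h1, h2):
        """Single explicit water plus a one-atom O donor/acceptor solute."""
        from gistlab.model_io import Atom, Frame, Topology

        atoms = [
            Atom(0, "OG", "O", "TOY", 1, 0, charge=0, lj_sigma=0, lj_epsilon=0,
                 mass=16, role="solute"),
            Atom(1, "HG", "H", "TOY", 1, 0, charge=0, lj_sigma=0, lj_epsilon=0,
                 mass=1, role="solute"),
            Atom(2, "O", "O", "WAT", 2, 1, charge=0, lj_sigma=0, lj_epsilon=0,
                 mass=16, role="water"),
            Atom(3, "H1", "H", "WAT", 2, 1, charge=0, lj_sigma=0, lj_epsilon=0,
                 mass=1, role="water"),
            Atom(4, "H2", "H", "WAT", 2, 1, charge=0, lj_sigma=0, lj_epsilon=0,
                 mass=1, role="water"),
        ]
        top = Topology(atoms, bonds=[(0, 1), (2, 3), (2, 4)])
        sol_h = np.array([0.0, 0.0, -1.0])
        coords = np.vstack(
            [np.zeros(3), sol_h, np.asarray(o), np.asarray(h1), np.asarray(h2)]
        )
        return top, Frame(coords)

    def _count(self, top, frame):
        rep = count_hbonds(frame, top, {0, 1}, partner_role="water")
        return rep.count

    def test_linear_geometry_counts_one(self):
        # water donates: O_w at 2.8 Å, H on the O_w -> O_solute axis
        top, frame = self._water_at(
            o=[2.8, 0.0, 0.0], h1=[1.84, 0.0, 0.0], h2=[3.4, 0.9, 0.0]
        )
        assert self._count(top, frame) == 1

    def test_distance_criterion(self):
        top, frame = self._water_at(
            o=[3.6, 0.0, 0.0], h1=[2.64, 0.0, 0.0], h2=[4.2, 0.9, 0.0]
        )
        assert self._count(top, frame) == 0

    def test_angle_criterion(self):
        # D-H...A angle of 120 degrees fails the 135-180 window
        o = np.array([2.8, 0.0, 0.0])
        h_dir = Rotation.from_euler("z", 60, degrees=True).apply([-1.0, 0.0, 0.0])
        top, frame = self._water_at(o=o, h1=o + 0.96 * h_dir, h2=o + [0.5, 0.9, 0.0])
        assert self._count(top, frame) == 0

    def test_both_directions_counted(self):
        # solute O-H donates to the water oxygen (water H's point away)
        top, frame = self._water_at(
            o=[0.0, 0.0, -2.8], h1=[0.6, 0.6, -3.3], h2=[-0.6, 0.6, -3.3]
        )
        # solute H at (0,0,-1) lies on the O...O_w axis: angle 180
        assert self._count(top, frame) == 1

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        top, frame = self._water_at(
            o=[2.8, 0.0, 0.0], h1=[1.84, 0.0, 0.0], h2=[3.4, 0.9, 0.0]
        )
        base = self._count(top, frame)
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-20, 20, 3)
        from gistlab.model_io import Frame

        moved = Frame(rot.apply(frame.coordinates) + shift)
        assert self._count(top, moved) == base

    def test_normalization_per_molecule(self):
        top, frame = self._water_at(
            o=[2.8, 0.0, 0.0], h1=[1.84, 0.0, 0.0], h2=[3.4, 0.9, 0.0]
        )
        rep = count_hbonds(frame, top, {0, 1}, partner_role="water")
        assert rep.n_partner_molecules == 1
        assert rep.normalized == rep.count / 1


class TestFormalCharge:
    @pytest.mark.parametrize(
        "seq,charge,ions",
        [
            ("ATCCTAGTTATAGGAT", -15, 15),  # 16-mer hairpin strand
            ("GGTTGGTGTGGTTGG", -14, 14),  # 15-mer quadruplex strand
            ("A", 0, 0),
        ],
    )
    def test_printed_values(self, seq, charge, ions):
        assert formal_net_charge(seq) == (charge, ions)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            formal_net_charge("")

    def test_dinucleotide_consistency(self, dinucleotide):
        top, _ = dinucleotide
        q, ions = formal_net_charge(["DG", "DT"])
        assert q == -1 and ions == 1
        assert top.charges.sum() == pytest.approx(q)
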