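"""Static-structure hydration metrics.

* Iso-minimum-distance shell surfaces around the solute (boundary of the
  union of per-atom spheres at radius r_min) and the bare-Coulomb average
  electrostatic potential on them, in e/Å.
* Atom-to-surface distance distributions (how deeply atoms are buried
  relative to a given shell).
* Shrake–Rupley solvent-accessible surface area on a deterministic Fibonacci
  sphere lattice, and the relative SASA probe scan
  ``R_SASA(r_p) = SASA(r_p) / SASA(r_0)`` with the water-probe reference
  r_0 = 1.4 Å. The scan probes whether surface pockets admit cosolute-sized
  probes.
* Geometric hydrogen-bond counting (donor-acceptor heavy-atom distance plus
  the angle at the hydrogen) normalized per partner molecule in a region.
* Formal net charge and neutralizing counterion count of an unmodified
  single-stranded nucleic acid (one negative charge per phosphodiester
  linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import BONDI_RADII, DEFAULT_RADIUS
from .errors import GeometryError, SelectionError, StructureError, SurfaceError
from .model_io import Frame, Topology
from .regions import RegionMask


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice of n points."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# Shell surface and electrostatic potential
# ---------------------------------------------------------------------------


@dataclass
class ShellSurface:
    """Points on the iso-minimum-distance surface at radius r_min."""

    r_min: float
    points: np.ndarray
    tolerance: float


def build_shell_surface(
    atom_coords: np.ndarray,
    r_min: float,
    points_per_atom: int = 256,
    tolerance: float = 1e-6,
) -> ShellSurface:
    """Boundary of the union of per-atom spheres of radius r_min.

    Candidate points lie on a deterministic spherical lattice around every
    atom; a candidate survives iff no atom of the set is closer than
    ``r_min - tolerance`` (its own sphere guarantees one atom at exactly
    r_min). Deterministic for a fixed resolution.
    """
    atoms = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    if atoms.size == 0 or r_min <= 0:
        raise ValueError("need a non-empty atom set and positive r_min")
    lattice = fibonacci_sphere(points_per_atom) * r_min
    candidates = (atoms[:, None, :] + lattice[None, :, :]).reshape(-1, 3)
    dmin, _ = cKDTree(atoms).query(candidates)
    keep = dmin >= r_min - tolerance
    if not keep.any():
        raise SurfaceError("no surface points survive; degenerate geometry")
    return ShellSurface(r_min=r_min, points=candidates[keep], tolerance=tolerance)


@dataclass
class PotentialProfile:
    """Average bare-Coulomb potential V(r_min) on shell surfaces, e/Å."""

    r_min: np.ndarray
    potential: np.ndarray
    n_points: np.ndarray
    n_atoms: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_min": self.r_min, "V": self.potential, "n_points": self.n_points}
        )


def shell_potential_profile(
    topology: Topology,
    frame: Frame,
    r_min_values,
    atom_indices=None,
    points_per_atom: int = 256,
) -> PotentialProfile:
    """Average ``sum_i q_i / r_ij`` over each shell surface (no dielectric).

    ``atom_indices`` restricts the charge-carrying atom set (default: all
    solute-role atoms).
    """
    if atom_indices is None:
        atom_indices = np.flatnonzero(topology.roles == "solute")
    atom_indices = np.asarray(sorted(atom_indices), dtype=int)
    q = topology.charges[atom_indices]
    if np.any(np.isnan(q)):
        raise StructureError("solute charges are unset")
    coords = frame.coordinates[atom_indices]
    r_min_values = np.atleast_1d(np.asarray(r_min_values, dtype=float))
    pot = np.empty(r_min_values.size)
    npts = np.empty(r_min_values.size, dtype=int)
    for k, rm in enumerate(r_min_values):
        surf = build_shell_surface(coords, rm, points_per_atom=points_per_atom)
        d = np.linalg.norm(
            surf.points[:, None, :] - coords[None, :, :], axis=2
        )
        if np.any(d < 1e-9):
            raise GeometryError("surface point coincides with an atom")
        pot[k] = float(np.mean((q[None, :] / d).sum(axis=1)))
        npts[k] = surf.points.shape[0]
    return PotentialProfile(
        r_min=r_min_values, potential=pot, n_points=npts, n_atoms=atom_indices.size
    )


def atom_surface_distance_distribution(
    atom_coords: np.ndarray, surface: ShellSurface, bin_width: float = 1.0
):
    """Surface-averaged distribution of atom distances from a shell surface.

    For every surface point the distances to all (distinct) atoms are
    binned; counts are averaged over surface points, so the histogram reads
    as the mean number of atoms per distance bin and its support ends at the
    envelope within which the surface "sees" every atom. Elongated solutes
    have a longer envelope than compact ones of equal atom count.

    Returns ``(mean_counts, bin_edges, max_distance)``.
    """
    atoms = np.unique(
        np.round(np.atleast_2d(np.asarray(atom_coords, dtype=float)), 9), axis=0
    )
    d = np.linalg.norm(
        surface.points[:, None, :] - atoms[None, :, :], axis=2
    ).ravel()
    dmax = float(d.max())
    edges = np.arange(0.0, dmax + 2 * bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return counts / surface.points.shape[0], edges, dmax


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def element_radii(topology: Topology, indices=None) -> np.ndarray:
    """Bondi van der Waals radii by element (configurable default set)."""
    if indices is None:
        indices = np.arange(topology.n_atoms)
    return np.array(
        [
            BONDI_RADII.get(str(topology.elements[i]).upper(), DEFAULT_RADIUS)
            for i in indices
        ]
    )


def sasa(
    atom_coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    per_atom: bool = False,
):
    """Shrake–Rupley solvent-accessible surface area, Å².

    Per atom, lattice points on the expanded sphere (radius + probe) count as
    accessible when inside no other atom's expanded sphere; the atom
    contributes its accessible fraction of the expanded-sphere area. The
    lattice is deterministic. With ``per_atom`` the per-atom areas (after
    identical-sphere deduplication) are returned instead of the total; any
    atom's own area can only grow when other atoms are removed.
    """
    atoms = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (atoms.shape[0],)).copy()
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    # exactly coincident equal spheres are one sphere; keep a single copy
    _, uniq = np.unique(
        np.round(np.column_stack([atoms, radii[:, None]]), 9), axis=0, return_index=True
    )
    atoms, radii = atoms[sorted(uniq)], radii[sorted(uniq)]
    expanded = radii + probe_radius
    lattice = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(atoms)
    areas = np.empty(atoms.shape[0])
    rmax = expanded.max()
    for i in range(atoms.shape[0]):
        pts = atoms[i] + expanded[i] * lattice
        neigh = [
            j
            for j in tree.query_ball_point(atoms[i], expanded[i] + rmax)
            if j != i
        ]
        if neigh:
            # tolerance keeps tangent spheres from occluding each other
            d = np.linalg.norm(pts[:, None, :] - atoms[neigh][None, :, :], axis=2)
            buried = (d < expanded[neigh][None, :] - 1e-9).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    if per_atom:
        return areas
    return float(areas.sum())


@dataclass
class SasaScan:
    """SASA versus probe radius plus ratios to the reference probe."""

    probe_radii: np.ndarray
    sasa_values: np.ndarray
    r0: float
    sasa_r0: float
    r_sasa: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_radius": self.probe_radii,
                "sasa": self.sasa_values,
                "r_sasa": self.r_sasa,
            }
        )


def rsasa_scan(
    atom_coords: np.ndarray,
    radii: np.ndarray,
    probe_radii,
    r0: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaScan:
    """Relative SASA ``SASA(r_p)/SASA(r_0)`` over a probe-radius list."""
    probe_radii = np.atleast_1d(np.asarray(probe_radii, dtype=float))
    values = np.array(
        [
            sasa(atom_coords, radii, rp, n_sphere_points=n_sphere_points)
            for rp in probe_radii
        ]
    )
    s0 = sasa(atom_coords, radii, r0, n_sphere_points=n_sphere_points)
    if s0 <= 0:
        raise GeometryError("reference SASA is zero; degenerate structure")
    return SasaScan(
        probe_radii=probe_radii,
        sasa_values=values,
        r0=r0,
        sasa_r0=s0,
        r_sasa=values / s0,
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    A bond requires donor/acceptor heavy-atom (N or O) distance below
    ``max_heavy_distance`` and a donor-H-acceptor angle inside
    [angle_lo, angle_hi] degrees.
    """

    max_heavy_distance: float = 3.5
    angle_lo: float = 135.0
    angle_hi: float = 180.0
    elements: tuple = ("N", "O")

    def __post_init__(self):
        if self.max_heavy_distance <= 0:
            raise ValueError("distance criterion must be positive")
        if not 0 <= self.angle_lo < self.angle_hi <= 180:
            raise ValueError("need 0 <= angle_lo < angle_hi <= 180")


@dataclass
class HBondReport:
    """H-bond counts between solute-region atoms and partner molecules."""

    count: int
    n_partner_molecules: int
    normalized: float
    pairs: list = field(default_factory=list)  # (donor, hydrogen, acceptor)


def _bonded_hydrogens(topology: Topology) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for i, j in topology.bonds:
        if topology.elements[i] == "H" and topology.elements[j] != "H":
            out.setdefault(j, []).append(i)
        elif topology.elements[j] == "H" and topology.elements[i] != "H":
            out.setdefault(i, []).append(j)
    return out


def _angle_at(h, d, a) -> float:
    v1 = d - h
    v2 = a - h
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def count_hbonds(
    frame: Frame,
    topology: Topology,
    solute_atoms,
    partner_role: str = "water",
    criteria: HBondCriteria | None = None,
    partner_region: RegionMask | None = None,
    partner_reference: str = "auto",
) -> HBondReport:
    """Count solute–partner hydrogen bonds in one frame.

    Both directions are counted (solute donor -> partner acceptor and
    partner donor -> solute acceptor). Partner molecules may be restricted to
    those whose reference point (water: oxygen; else geometric center of
    heavy atoms) lies inside a region mask; the count is also normalized by
    the number of partner molecules considered.
    """
    criteria = criteria or HBondCriteria()
    solute_atoms = np.asarray(sorted(solute_atoms), dtype=int)
    if solute_atoms.size == 0:
        raise SelectionError("empty solute atom set")
    coords = frame.coordinates
    mask = frame.active_mask()
    hydro = _bonded_hydrogens(topology)

    # Partner molecules, optionally restricted to a region.
    partner_mols = []
    for members in topology.molecule_members(partner_role):
        members = members[mask[members]]
        if members.size == 0:
            continue
        partner_mols.append(members)
    if partner_region is not None:
        kept = []
        member_mask = partner_region.member_mask()
        for members in partner_mols:
            if partner_reference == "auto":
                rule = "oxygen" if partner_role == "water" else "geometric_center"
            else:
                rule = partner_reference
            if rule == "oxygen":
                ox = members[
                    np.array([topology.elements[i] == "O" for i in members])
                ]
                ref = coords[ox[0]]
            else:
                heavy = members[
                    np.array([topology.elements[i] != "H" for i in members])
                ]
                ref = coords[heavy if heavy.size else members].mean(axis=0)
            v = partner_region.grid.voxel_indices(ref)[0]
            if v >= 0 and member_mask[v]:
                kept.append(members)
        partner_mols = kept

    def heavy_of(indices):
        return [i for i in indices if topology.elements[i] in criteria.elements]

    def donors_of(indices):
        out = []
        for i in heavy_of(indices):
            hs = [h for h in hydro.get(i, []) if mask[h]]
            if topology.elements[i] in criteria.elements and hs:
                out.append((i, hs))
            elif topology.roles[i] == "water" and not hs:
                raise StructureError(f"water donor {i} has no bonded hydrogens")
        return out

    sol_heavy = heavy_of(solute_atoms[mask[solute_atoms]])
    sol_donors = donors_of(solute_atoms[mask[solute_atoms]])

    pairs = []
    for members in partner_mols:
        p_heavy = heavy_of(members)
        p_donors = donors_of(members)
        # solute donor -> partner acceptor, and partner donor -> solute acceptor
        for donors, acceptors in ((sol_donors, p_heavy), (p_donors, sol_heavy)):
            for d, hs in donors:
                for a in acceptors:
                    if a == d:
                        continue
                    if (
                        np.linalg.norm(coords[d] - coords[a])
                        >= criteria.max_heavy_distance
                    ):
                        continue
                    for h in hs:
                        ang = _angle_at(coords[h], coords[d], coords[a])
                        if criteria.angle_lo <= ang <= criteria.angle_hi:
                            pairs.append((int(d), int(h), int(a)))
                            break
    n_partner = len(partner_mols)
    return HBondReport(
        count=len(pairs),
        n_partner_molecules=n_partner,
        normalized=len(pairs) / n_partner if n_partner else 0.0,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Formal charge
# ---------------------------------------------------------------------------


def formal_net_charge(sequence) -> tuple[int, int]:
    """Formal net charge (e) and neutralizing counterion count of an ssDNA.

    An unmodified strand without terminal phosphates carries one negative
    charge per phosphodiester linkage: ``-(n_residues - 1)``.
    """
    if isinstance(sequence, str):
        n = len(sequence.strip())
    else:
        n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    linkages = n - 1
    return -linkages, linkages
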