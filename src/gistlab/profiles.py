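"""Minimum-distance-resolved solvent/cosolute density profiles.

The number-density profile of a species is the voxel average of
``n_molecule(r_k) / V_k`` over the voxels whose center's minimum distance to
the solute falls in each half-open bin [r, r + Δr). A molecule is located by
one reference point: water by its oxygen, a cosolute by the geometric center
of its heavy atoms (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import RHO0_BULK
from .errors import SelectionError
from .model_io import Trajectory
from .regions import RegionMask, RminField


@dataclass
class ProfileSpec:
    """Species selector and binning for a density profile."""

    species: str = "water"  # role: water | cosolute | ion
    delta_r: float = 0.5  # bin width, Å
    r_max: float = 12.0  # profile range upper edge, Å
    rho0: float = RHO0_BULK  # reference density for the relative profile
    reference: str = "auto"  # auto | oxygen | geometric_center

    def __post_init__(self):
        if self.delta_r <= 0:
            raise ValueError("bin width must be positive")


@dataclass
class ProfileTable:
    """Density profile; ``undefined`` flags bins containing no voxels."""

    r_lower: np.ndarray  # bin lower edges, Å
    rho: np.ndarray  # Å^-3 (NaN where undefined)
    rho_over_rho0: np.ndarray
    n_voxels: np.ndarray
    undefined: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_min": self.r_lower,
                "rho": self.rho,
                "rho_over_rho0": self.rho_over_rho0,
                "n_voxels": self.n_voxels,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _reference_points(trajectory: Trajectory, frame, species: str, reference: str):
    """Per-molecule reference coordinates for one frame (may be empty)."""
    top = trajectory.topology
    mask = frame.active_mask()
    if reference == "auto":
        reference = "oxygen" if species == "water" else "geometric_center"
    pts = []
    for members in top.molecule_members(species):
        members = members[mask[members]]
        if members.size == 0:
            continue
        if reference == "oxygen":
            ox = members[np.array([top.elements[i] == "O" for i in members])]
            if ox.size == 0:
                raise SelectionError(f"{species} molecule lacks an oxygen")
            pts.append(frame.coordinates[ox[0]])
        elif reference == "geometric_center":
            heavy = members[np.array([top.elements[i] != "H" for i in members])]
            use = heavy if heavy.size else members
            pts.append(frame.coordinates[use].mean(axis=0))
        else:
            raise ValueError(f"unknown reference rule {reference!r}")
    return np.array(pts).reshape(-1, 3)


def species_voxel_counts(
    trajectory: Trajectory, field_or_grid, species: str, reference: str = "auto"
) -> np.ndarray:
    """Mean per-frame molecule count per voxel for one species."""
    grid = getattr(field_or_grid, "grid", field_or_grid)
    counts = np.zeros(grid.n_voxels)
    for frame in trajectory:
        pts = _reference_points(trajectory, frame, species, reference)
        if pts.size == 0:
            continue
        vox = grid.voxel_indices(pts)
        inside = vox >= 0
        if inside.any():
            counts += np.bincount(vox[inside], minlength=grid.n_voxels)
    return counts / trajectory.frame_count


def min_distance_density_profile(
    trajectory: Trajectory, field: RminField, spec: ProfileSpec
) -> ProfileTable:
    """Species number density versus minimum distance to the solute."""
    grid = field.grid
    n_mol = species_voxel_counts(trajectory, grid, spec.species, spec.reference)
    edges = np.arange(0.0, spec.r_max + spec.delta_r * 0.5, spec.delta_r)
    lowers = edges[:-1] if edges.size > 1 else edges
    nbins = lowers.size
    rho = np.full(nbins, np.nan)
    nvox = np.zeros(nbins, dtype=int)
    bin_of = np.floor(field.values / spec.delta_r).astype(int)
    for b in range(nbins):
        members = np.flatnonzero(bin_of == b)
        nvox[b] = members.size
        if members.size:
            rho[b] = float(np.mean(n_mol[members])) / grid.voxel_volume
    return ProfileTable(
        r_lower=lowers,
        rho=rho,
        rho_over_rho0=rho / spec.rho0,
        n_voxels=nvox,
        undefined=nvox == 0,
    )


def region_population_series(
    trajectory: Trajectory,
    mask: RegionMask,
    species: str = "water",
    reference: str = "auto",
) -> np.ndarray:
    """Per-frame integer count of species molecules inside a region.

    The mean of the series equals the region's n(R) for water when the same
    oxygen reference rule is used.
    """
    member = mask.member_mask()
    counts = np.zeros(trajectory.frame_count, dtype=int)
    for fi, frame in enumerate(trajectory):
        pts = _reference_points(trajectory, frame, species, reference)
        if pts.size == 0:
            continue
        vox = mask.grid.voxel_indices(pts)
        inside = vox >= 0
        counts[fi] = int(member[vox[inside]].sum())
    return counts
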