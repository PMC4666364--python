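"""Minimum-distance regions and per-water region thermodynamics.

A region is the set of voxels whose center lies strictly between two bounds
of the minimum distance r_min to a designated solute atom set (the first
hydration shell is 2 Å < r_min < 4 Å around the whole solute; local shells
use base or phosphate-group atom subsets). VoxelMap quantities aggregate to
per-water values by normalizing extensive voxel sums with the mean water
count n(R).

The bulk water–water reference for a region is density-corrected:
``E_ww^0(R) = rho0 * V(R) * eps_ww0`` rather than ``n(R) * eps_ww0``, so a
region denser (sparser) than bulk is no longer under- (over-) credited with
bulk water–water energy. The per-water free energy then composes as
``dG^w = -TdS_tr^w - TdS_or^w + dE_sw^w + dE_ww^w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyRegionError, IncompatibleError
from .gist import BulkReference, Grid, VoxelMap


@dataclass
class RminField:
    """Minimum distance from an atom set to every voxel center (Å)."""

    grid: Grid
    values: np.ndarray  # flat, grid C order


def rmin_field(grid: Grid, atom_coords: np.ndarray) -> RminField:
    """Exact minimum Euclidean distance field over voxel centers."""
    atom_coords = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    if atom_coords.size == 0:
        raise ValueError("atom set must be non-empty")
    dist, _ = cKDTree(atom_coords).query(grid.centers())
    return RminField(grid=grid, values=np.asarray(dist))


@dataclass
class RegionMask:
    """Voxel membership of one minimum-distance region."""

    grid: Grid
    members: np.ndarray  # sorted flat voxel indices
    lo: float = np.nan
    hi: float = np.nan

    @property
    def volume(self) -> float:
        """V(R): summed voxel volume, Å³."""
        return float(self.members.size * self.grid.voxel_volume)

    def member_mask(self) -> np.ndarray:
        m = np.zeros(self.grid.n_voxels, dtype=bool)
        m[self.members] = True
        return m


def region_from_rmin(field: RminField, lo: float, hi: float) -> RegionMask:
    """Voxels with ``lo < r_min < hi`` (strict at both bounds)."""
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi")
    members = np.flatnonzero((field.values > lo) & (field.values < hi))
    return RegionMask(grid=field.grid, members=members, lo=lo, hi=hi)


@dataclass
class RegionSummary:
    """Per-water thermodynamics of one region (kcal/mol at temperature T)."""

    n: float  # mean water count n(R)
    volume: float  # V(R), Å³
    rho: float  # n(R)/V(R), Å^-3
    tds_tr_w: float
    tds_or_w: float
    de_sw_w: float
    de_ww_w: float
    dg_w: float
    temperature: float
    bulk: BulkReference

    @property
    def rho_over_rho0(self) -> float:
        return self.rho / self.bulk.rho0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "volume": self.volume,
            "rho": self.rho,
            "rho_over_rho0": self.rho_over_rho0,
            "TdS_tr_w": self.tds_tr_w,
            "TdS_or_w": self.tds_or_w,
            "dE_sw_w": self.de_sw_w,
            "dE_ww_w": self.de_ww_w,
            "dG_w": self.dg_w,
            "temperature": self.temperature,
        }


def region_summary(
    voxelmap: VoxelMap, mask: RegionMask, bulk: BulkReference
) -> RegionSummary:
    """Aggregate a complete VoxelMap over a region to per-water values.

    Requires density, energies and entropies on the map. The water–solute
    bulk reference is zero (no solute in bulk); the water–water reference is
    the density-corrected ``rho0 V(R) eps_ww0``.
    """
    for name in ("E_sw", "E_ww", "TdS_tr", "TdS_or"):
        if getattr(voxelmap, name) is None:
            raise ValueError(f"voxelmap is missing {name}; run the full pipeline")
    m = mask.members
    if m.size == 0:
        raise EmptyRegionError("region contains no voxels")
    n_R = float(voxelmap.n[m].sum())
    if n_R <= 0:
        raise EmptyRegionError("region contains no water")
    V_R = mask.volume
    rho_R = n_R / V_R
    tds_tr_w = float(voxelmap.TdS_tr[m].sum()) / n_R
    tds_or_w = float(voxelmap.TdS_or[m].sum()) / n_R
    de_sw_w = float(voxelmap.E_sw[m].sum()) / n_R
    e_ww_R = float(voxelmap.E_ww[m].sum())
    de_ww_w = (e_ww_R - bulk.rho0 * V_R * bulk.eps_ww0) / n_R
    dg_w = -tds_tr_w - tds_or_w + de_sw_w + de_ww_w
    return RegionSummary(
        n=n_R,
        volume=V_R,
        rho=rho_R,
        tds_tr_w=tds_tr_w,
        tds_or_w=tds_or_w,
        de_sw_w=de_sw_w,
        de_ww_w=de_ww_w,
        dg_w=dg_w,
        temperature=bulk.temperature,
        bulk=bulk,
    )


_DIFF_FIELDS = ("tds_tr_w", "tds_or_w", "de_sw_w", "de_ww_w", "dg_w")


@dataclass
class RegionDifference:
    """Componentwise b - a differences of per-water thermodynamics."""

    d_n: float
    d_tds_tr_w: float
    d_tds_or_w: float
    d_de_sw_w: float
    d_de_ww_w: float
    d_dg_w: float
    sem: dict | None = None  # per-component standard errors, when available

    def to_dict(self) -> dict:
        out = {
            "d_n": self.d_n,
            "d_TdS_tr_w": self.d_tds_tr_w,
            "d_TdS_or_w": self.d_tds_or_w,
            "d_dE_sw_w": self.d_de_sw_w,
            "d_dE_ww_w": self.d_de_ww_w,
            "d_dG_w": self.d_dg_w,
        }
        if self.sem:
            out["sem"] = dict(self.sem)
        return out


def _block_sem(blocks: list[RegionSummary], attr: str) -> float:
    vals = np.array([getattr(b, attr) for b in blocks], dtype=float)
    if vals.size < 2:
        return float("nan")
    return float(vals.std(ddof=1) / np.sqrt(vals.size))


def compare_conditions(
    a: RegionSummary,
    b: RegionSummary,
    blocks_a: list[RegionSummary] | None = None,
    blocks_b: list[RegionSummary] | None = None,
) -> RegionDifference:
    """Difference record b - a (e.g. with/without cosolute).

    When per-block summaries are supplied for both conditions, per-component
    standard errors are propagated as sqrt(sem_a^2 + sem_b^2) of the block
    means.
    """
    if a.temperature != b.temperature or a.bulk != b.bulk:
        raise IncompatibleError("summaries use different bulk references")
    sem = None
    if blocks_a and blocks_b:
        sem = {
            f: float(np.hypot(_block_sem(blocks_a, f), _block_sem(blocks_b, f)))
            for f in _DIFF_FIELDS
        }
    return RegionDifference(
        d_n=b.n - a.n,
        d_tds_tr_w=b.tds_tr_w - a.tds_tr_w,
        d_tds_or_w=b.tds_or_w - a.tds_or_w,
        d_de_sw_w=b.de_sw_w - a.de_sw_w,
        d_de_ww_w=b.de_ww_w - a.de_ww_w,
        d_dg_w=b.dg_w - a.dg_w,
        sem=sem,
    )


def summaries_to_frame(rows: dict[str, RegionSummary]) -> pd.DataFrame:
    """Tabulate named region summaries (one row per region)."""
    return pd.DataFrame({k: v.to_dict() for k, v in rows.items()}).T
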