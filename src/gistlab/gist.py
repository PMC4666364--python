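"""Voxel-grid solvation thermodynamics.

A cubic-voxel grid is populated from an ensemble of solvent frames: a water
lies in voxel k when its oxygen is inside the voxel (half-open intervals, so
a coordinate exactly on a boundary belongs to the upper voxel). Per voxel the
engine accumulates

* ``n(r_k)`` — mean water count per frame, and the relative density
  ``g(r_k) = n(r_k) / (rho0 * V_k)``,
* ``E_sw(r_k)`` — mean summed water–solute interaction energy of the waters
  in the voxel (Coulomb + Lennard-Jones, minimum image),
* ``E_ww(r_k)`` — mean water–water interaction energy, each molecular pair
  energy attributed half to each partner's voxel so the voxel sum equals the
  total water–water energy,
* ``TΔS_tr(r_k)`` — translational solvation entropy from the first-order
  density formula ``-kB T n ln g``,
* ``TΔS_or(r_k)`` — orientational solvation entropy from a first-nearest-
  neighbour entropy estimate over the water orientations observed in the
  voxel (quaternions on the rotation manifold).

Water orientations use a body frame with z along the H-O-H bisector and x in
the molecular plane (towards the first hydrogen); antipodal quaternions are
identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import COULOMB_K, KB_KCAL
from .errors import GeometryError, MissingParameterError, StructureError
from .model_io import Trajectory

EULER_GAMMA = 0.5772156649015329
OMEGA_SO3 = 4.0 * np.pi**2  # Haar volume of the rotation manifold


@dataclass(frozen=True)
class Grid:
    """Regular cubic-voxel grid; membership is half-open per axis."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(self.dims)

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Flat voxel index per point; -1 for points outside the grid."""
        points = np.atleast_2d(points)
        rel = (points - np.asarray(self.origin)) / self.spacing
        ijk = np.floor(rel).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.asarray(self.dims)), axis=1)
        flat = np.full(points.shape[0], -1, dtype=int)
        if inside.any():
            flat[inside] = np.ravel_multi_index(ijk[inside].T, self.dims)
        return flat

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) voxel-center coordinates in flat (C) order."""
        axes = [
            self.origin[a] + self.spacing * (np.arange(self.dims[a]) + 0.5)
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_grid(bounds_min, bounds_max, spacing: float = 0.5) -> Grid:
    """Grid covering the box [bounds_min, bounds_max] (dims rounded up)."""
    lo = np.asarray(bounds_min, dtype=float)
    hi = np.asarray(bounds_max, dtype=float)
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if np.any(hi <= lo):
        raise ValueError("bounds_max must exceed bounds_min on every axis")
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / spacing - 1e-9)) for a in range(3))
    return Grid(origin=tuple(lo), spacing=spacing, dims=dims)


def grid_around(coords: np.ndarray, margin: float = 7.0, spacing: float = 0.5) -> Grid:
    """Grid covering the atom bounding box plus a margin on every side."""
    coords = np.atleast_2d(coords)
    return build_grid(coords.min(axis=0) - margin, coords.max(axis=0) + margin, spacing)


@dataclass(frozen=True)
class BulkReference:
    """Bulk-water reference constants."""

    rho0: float = 0.0329  # number density, Å^-3
    eps_ww0: float = -9.565  # per-water water-water energy, kcal/mol
    temperature: float = 298.0  # K

    def __post_init__(self):
        if self.rho0 <= 0 or self.temperature <= 0:
            raise ValueError("rho0 and temperature must be positive")


@dataclass
class VoxelMap:
    """Per-voxel solvation quantities (flat arrays in grid C order)."""

    grid: Grid
    n_frames: int
    n: np.ndarray
    g: np.ndarray
    E_sw: np.ndarray | None = None
    E_ww: np.ndarray | None = None
    TdS_tr: np.ndarray | None = None
    TdS_or: np.ndarray | None = None
    orientations: dict[int, np.ndarray] = field(default_factory=dict)
    sparse_orientation_voxels: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        centers = self.grid.centers()
        cols = {
            "voxel": np.arange(self.grid.n_voxels),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "z": centers[:, 2],
            "n": self.n,
            "g": self.g,
        }
        for name in ("E_sw", "E_ww", "TdS_tr", "TdS_or"):
            arr = getattr(self, name)
            if arr is not None:
                cols[name] = arr
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Occupancy + orientations
# ---------------------------------------------------------------------------


def water_orientations(o, h1, h2) -> np.ndarray:
    """Unit quaternions (x, y, z, w) for rigid waters from site coordinates.

    Body frame: z along the H-O-H bisector, x in the molecular plane towards
    H1, y = z × x. The sign is canonicalized (w >= 0) since antipodal
    quaternions describe the same orientation.
    """
    a = h1 - o
    b = h2 - o
    na = np.linalg.norm(a, axis=-1, keepdims=True)
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    if np.any(na <= 0) or np.any(nb <= 0):
        raise StructureError("water hydrogen coincides with oxygen")
    a = a / na
    b = b / nb
    z = a + b
    nz = np.linalg.norm(z, axis=-1, keepdims=True)
    if np.any(nz <= 1e-12):
        raise StructureError("degenerate (linear) water geometry")
    z = z / nz
    x = a - np.sum(a * z, axis=-1, keepdims=True) * z
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    y = np.cross(z, x)
    mats = np.stack([x, y, z], axis=-1)  # columns are body axes in lab frame
    quats = Rotation.from_matrix(mats).as_quat().reshape(-1, 4)
    flip = quats[:, 3] < 0
    quats[flip] *= -1.0
    return quats


def accumulate_voxel_stats(
    trajectory: Trajectory, grid: Grid, bulk: BulkReference | None = None
) -> VoxelMap:
    """Mean per-voxel water occupancy, relative density and orientations."""
    bulk = bulk or BulkReference()
    top = trajectory.topology
    trip = top.water_triplets()
    if trip.size == 0:
        raise StructureError("trajectory contains no waters")
    counts = np.zeros(grid.n_voxels)
    orient: dict[int, list[np.ndarray]] = {}
    for frame in trajectory:
        mask = frame.active_mask()
        live = trip[mask[trip[:, 0]]]
        if live.size == 0:
            continue
        coords = frame.coordinates
        vox = grid.voxel_indices(coords[live[:, 0]])
        inside = vox >= 0
        if not inside.any():
            continue
        counts += np.bincount(vox[inside], minlength=grid.n_voxels)
        quats = water_orientations(
            coords[live[inside, 0]], coords[live[inside, 1]], coords[live[inside, 2]]
        )
        for v, q in zip(vox[inside], quats):
            orient.setdefault(int(v), []).append(q)
    n = counts / trajectory.frame_count
    g = n / (bulk.rho0 * grid.voxel_volume)
    orientations = {v: np.vstack(qs) for v, qs in orient.items()}
    return VoxelMap(
        grid=grid,
        n_frames=trajectory.frame_count,
        n=n,
        g=g,
        orientations=orientations,
    )


# ---------------------------------------------------------------------------
# Pairwise interaction energies
# ---------------------------------------------------------------------------


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def _pair_energy_matrix(ci, cj, qi, qj, si, sj, ei, ej, box, cutoff):
    """(len(i), len(j)) matrix of Coulomb + LJ pair energies."""
    d = _min_image(ci[:, None, :] - cj[None, :, :], box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = COULOMB_K * np.outer(qi, qj) / r
        eps = np.sqrt(np.outer(ei, ej))
        lj_mask = eps > 0
        if lj_mask.any():
            sig = 0.5 * (si[:, None] + sj[None, :])
            sr6 = np.where(lj_mask, (sig / r) ** 6, 0.0)
            e = e + 4.0 * eps * (sr6**2 - sr6)
    if cutoff is not None:
        e = np.where(r <= cutoff, e, 0.0)
    return e, r


def voxel_energies(
    trajectory: Trajectory,
    grid: Grid,
    cutoff: float | None = None,
    voxelmap: VoxelMap | None = None,
) -> VoxelMap:
    """Mean per-voxel water–solute and water–water interaction energies.

    ``E_sw`` sums each in-voxel water's full interaction with every non-water
    atom; ``E_ww`` attributes half of each water–water molecular pair energy
    to each partner's voxel, so the voxel sum reproduces the total
    water–water energy. Intramolecular pairs are excluded; the minimum-image
    convention applies when the frame has a box. By default no cutoff is
    applied.
    """
    top = trajectory.topology
    need = np.isnan(top.charges) | np.isnan(top.lj_sigma) | np.isnan(top.lj_epsilon)
    if need.any():
        raise MissingParameterError(
            "unset force-field parameters for atoms "
            + ", ".join(sorted({top.names[i] for i in np.flatnonzero(need)[:10]}))
        )
    if voxelmap is None:
        voxelmap = accumulate_voxel_stats(trajectory, grid)
    trip = top.water_triplets()
    water_atoms = trip.ravel()
    other_atoms = np.flatnonzero(top.roles != "water")
    e_sw = np.zeros(grid.n_voxels)
    e_ww = np.zeros(grid.n_voxels)

    zero_energy = (
        np.all(top.charges == 0)
        and np.all(top.lj_epsilon == 0)
    )
    if not zero_energy:
        for frame in trajectory:
            mask = frame.active_mask()
            live = trip[mask[trip[:, 0]]]
            if live.size == 0:
                continue
            coords = frame.coordinates
            wsel = live.ravel()  # O,H,H per molecule, contiguous
            cw = coords[wsel]
            nmol = live.shape[0]
            vox = grid.voxel_indices(coords[live[:, 0]])
            inside = vox >= 0

            ew, rw = _pair_energy_matrix(
                cw, cw,
                top.charges[wsel], top.charges[wsel],
                top.lj_sigma[wsel], top.lj_sigma[wsel],
                top.lj_epsilon[wsel], top.lj_epsilon[wsel],
                frame.box, cutoff,
            )
            mol = np.repeat(np.arange(nmol), 3)
            same = mol[:, None] == mol[None, :]
            if np.any((rw < 1e-9) & ~same):
                raise GeometryError("coincident atoms in distinct molecules")
            ew = np.where(same, 0.0, ew)
            per_mol = ew.sum(axis=1).reshape(nmol, 3).sum(axis=1)
            half = 0.5 * per_mol
            np.add.at(e_ww, vox[inside], half[inside])

            if other_atoms.size:
                live_other = other_atoms[mask[other_atoms]]
                if live_other.size:
                    es, rs = _pair_energy_matrix(
                        cw, coords[live_other],
                        top.charges[wsel], top.charges[live_other],
                        top.lj_sigma[wsel], top.lj_sigma[live_other],
                        top.lj_epsilon[wsel], top.lj_epsilon[live_other],
                        frame.box, cutoff,
                    )
                    if np.any(rs < 1e-9):
                        raise GeometryError("water atom coincides with solute atom")
                    sw_mol = es.sum(axis=1).reshape(nmol, 3).sum(axis=1)
                    np.add.at(e_sw, vox[inside], sw_mol[inside])
        e_sw /= trajectory.frame_count
        e_ww /= trajectory.frame_count
    voxelmap.E_sw = e_sw
    voxelmap.E_ww = e_ww
    return voxelmap


# ---------------------------------------------------------------------------
# Entropy estimators
# ---------------------------------------------------------------------------


def trans_entropy_map(voxelmap: VoxelMap, bulk: BulkReference) -> VoxelMap:
    """Translational solvation entropy, first-order density formula.

    Per voxel ``TΔS_tr(r_k) = -kB T n(r_k) ln g(r_k)`` (zero where the voxel
    is empty); the per-water value is ``-kB T ln g``.
    """
    g = voxelmap.g
    out = np.zeros_like(g)
    pos = g > 0
    out[pos] = -KB_KCAL * bulk.temperature * voxelmap.n[pos] * np.log(g[pos])
    voxelmap.TdS_tr = out
    return voxelmap


def geodesic_ball_volume(r) -> np.ndarray:
    """Haar volume of a geodesic ball of radius r (radians) in SO(3)."""
    r = np.asarray(r, dtype=float)
    return 4.0 * np.pi * (r - np.sin(r))


def quaternion_nn_distances(quats: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """First-nearest-neighbour rotation angles (radians) within a sample.

    The metric is the rotation angle ``theta = 2 arccos(|q_i . q_j|)`` in
    [0, pi], which identifies antipodal quaternions.
    """
    q = np.asarray(quats, dtype=float)
    n = q.shape[0]
    if n < 2:
        raise ValueError("need at least two orientations")
    best = np.full(n, -np.inf)
    for start in range(0, n, chunk):
        block = q[start : start + chunk]
        dots = np.abs(block @ q.T)
        rows = np.arange(block.shape[0])
        dots[rows, start + rows] = -np.inf  # exclude self
        best[start : start + chunk] = dots.max(axis=1)
    return 2.0 * np.arccos(np.clip(best, -1.0, 1.0))


def nn_orientational_entropy(quats: np.ndarray, floor: float = 1e-6) -> float:
    """First-NN differential-entropy estimate on SO(3), in nats.

    ``H ≈ gamma + (1/N) sum_i ln(N * B(d_i))`` with ``B(r) = 4 pi (r - sin r)``
    and d_i the nearest-neighbour rotation angle (floored at ``floor`` rad).
    For Haar-uniform samples H approaches ``ln(4 pi^2)``.
    """
    d = np.maximum(quaternion_nn_distances(quats), floor)
    n = d.shape[0]
    return float(EULER_GAMMA + np.mean(np.log(n * geodesic_ball_volume(d))))


def relative_orientational_entropy(quats: np.ndarray) -> float:
    """``H - ln Omega`` in nats (0 for Haar-uniform, negative if ordered)."""
    return nn_orientational_entropy(quats) - float(np.log(OMEGA_SO3))


def orient_entropy_map(
    voxelmap: VoxelMap, bulk: BulkReference, min_samples: int = 10
) -> VoxelMap:
    """Orientational solvation entropy per voxel from stored orientations.

    Per voxel the per-water value is ``kB T (H - ln Omega)`` clamped to <= 0
    (the bulk reference being Haar-uniform); the voxel entry is scaled by
    ``n(r_k)`` so region sums normalize per Eq.-style bookkeeping. Voxels
    with fewer than ``min_samples`` observations report 0 and are flagged.
    """
    out = np.zeros(voxelmap.grid.n_voxels)
    sparse = []
    kbt = KB_KCAL * bulk.temperature
    for v, quats in voxelmap.orientations.items():
        if quats.shape[0] < min_samples:
            sparse.append(v)
            continue
        per_water = kbt * relative_orientational_entropy(quats)
        out[v] = voxelmap.n[v] * min(0.0, per_water)
    voxelmap.TdS_or = out
    voxelmap.sparse_orientation_voxels = np.array(sorted(sparse), dtype=int)
    return voxelmap


# ---------------------------------------------------------------------------
# OpenDX export
# ---------------------------------------------------------------------------


def write_dx(grid: Grid, values: np.ndarray, path, name: str = "gist") -> None:
    """Write one scalar voxel quantity as an OpenDX regular grid."""
    nx, ny, nz = grid.dims
    ox, oy, oz = (
        grid.origin[0] + grid.spacing / 2,
        grid.origin[1] + grid.spacing / 2,
        grid.origin[2] + grid.spacing / 2,
    )
    vals = np.asarray(values).reshape(nx * ny * nz)
    with open(path, "w") as fh:
        fh.write(f"# {name}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {grid.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for start in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[start : start + 3]) + "\n")
        fh.write(f'object "{name}" class field\n')
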