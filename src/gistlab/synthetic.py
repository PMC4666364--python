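"""Synthetic solvent ensembles with known statistical structure.

The generators place non-interacting ("ideal-gas") rigid 3-site waters, so
density and entropy targets are analytic: per-voxel counts are Poisson with
mean ``g(r_k) * rho0 * V_k``, orientations are drawn from a one-parameter
family that is Haar-uniform at concentration 0, and prescribed shell
profiles are recovered by the analysis stages in expectation. Liquid-water
realism (correlated positions, hydrogen-bond networks) is explicitly not
emulated.

The shell generator discretizes its target g(r_min) on its own analysis-
compatible voxel grid (r_min measured from voxel centers), so the expected
occupancy of voxel k is exactly ``g(r_k) rho0 V_k`` — the same uniform-
within-voxel convention the analysis assumes.

Also here: the brute-force oracles (O(N²) pair-energy totals, an
independent occupancy histogram, Monte-Carlo SASA) used to cross-check the
vectorized engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .constants import (
    COULOMB_K,
    RHO0_BULK,
    WATER_HOH_ANGLE,
    WATER_OH_LENGTH,
)
from .errors import GeneratorError
from .gist import Grid, build_grid
from .model_io import (
    DEFAULT_WATER_PARAMS,
    Atom,
    Frame,
    Topology,
    Trajectory,
)

# Rigid water body frame: z along the H-O-H bisector, x in the molecular
# plane towards H1 — the same convention the engine uses to read
# orientations back, so a water placed with quaternion q reports exactly q.
_HALF = math.radians(WATER_HOH_ANGLE / 2.0)
WATER_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],
        [WATER_OH_LENGTH * math.sin(_HALF), 0.0, WATER_OH_LENGTH * math.cos(_HALF)],
        [-WATER_OH_LENGTH * math.sin(_HALF), 0.0, WATER_OH_LENGTH * math.cos(_HALF)],
    ]
)

#: Rigid two-site toy cosolute: an O site and a C site 2.0 Å apart, with
#: stated arbitrary charges (net neutral) and modest LJ parameters.
COSOLUTE_SITES = (
    ("O1", "O", -0.3, 3.0, 0.15, 15.9994),
    ("C1", "C", 0.3, 3.4, 0.10, 12.011),
)
COSOLUTE_BOND_LENGTH = 2.0

ZERO_WATER_PARAMS = {"O": (0.0, 0.0, 0.0, 15.9994), "H": (0.0, 0.0, 0.0, 1.008)}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------


def ball_radius_from_kappa(kappa: float) -> float:
    """Geodesic-ball radius (rad) for a concentration parameter.

    kappa = 0 maps to the full manifold (radius pi, i.e. Haar-uniform);
    increasing kappa shrinks the ball monotonically.
    """
    if kappa < 0:
        raise ValueError("concentration must be >= 0")
    return math.pi / (1.0 + kappa)


def gen_orientation_samples(
    n: int,
    kappa: float = 0.0,
    seed=None,
    ball_radius: float | None = None,
) -> np.ndarray:
    """Unit quaternions (x, y, z, w), canonical sign w >= 0.

    Samples are Haar-uniform within a geodesic ball of the given radius
    about the identity (axis uniform on the sphere, rotation angle with the
    Haar density ∝ 1 - cos(theta) truncated to [0, radius]). ``kappa = 0``
    (radius pi) is exactly Haar-uniform over all orientations; the relative
    entropy of the uniform-in-ball mode has the closed form
    ``ln(B(r) / (4 pi^2))`` with ``B(r) = 4 pi (r - sin r)``.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = _rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = ball_radius if ball_radius is not None else ball_radius_from_kappa(kappa)
    if not 0 < r <= math.pi:
        raise ValueError("ball radius must lie in (0, pi]")
    # inverse-CDF sampling of theta with F(t) = (t - sin t)/(r - sin r)
    grid = np.linspace(0.0, r, 4096)
    cdf = (grid - np.sin(grid)) / (r - math.sin(r))
    theta = np.interp(rng.uniform(size=n), cdf, grid)
    axis = rng.normal(size=(n, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    half = theta / 2.0
    quats = np.column_stack([np.sin(half)[:, None] * axis, np.cos(half)])
    flip = quats[:, 3] < 0
    quats[flip] *= -1.0
    return quats


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from (x, y, z, w) quaternions; vectorized."""
    x, y, z, w = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack(
        [
            np.stack(
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                axis=-1,
            ),
            np.stack(
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                axis=-1,
            ),
            np.stack(
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                axis=-1,
            ),
        ],
        axis=-2,
    )


def water_site_coords(o_positions: np.ndarray, quats: np.ndarray) -> np.ndarray:
    """(n, 3, 3) lab coordinates [O, H1, H2] for placed rigid waters."""
    mats = _quat_to_matrix(quats)
    sites = np.einsum("nij,kj->nki", mats, WATER_TEMPLATE)
    return sites + o_positions[:, None, :]


# ---------------------------------------------------------------------------
# Topology builders
# ---------------------------------------------------------------------------


def _water_param_set(which: str) -> dict:
    if which == "tip3p":
        return DEFAULT_WATER_PARAMS
    if which == "zero":
        return ZERO_WATER_PARAMS
    raise ValueError("water_params must be 'tip3p' or 'zero'")


def _build_topology(
    solute_atoms: list[Atom],
    n_water_slots: int,
    n_cosolute_slots: int = 0,
    water_params: str = "tip3p",
) -> Topology:
    wp = _water_param_set(water_params)
    atoms = [a for a in solute_atoms]
    idx = len(atoms)
    mol = (max((a.molecule_id for a in atoms), default=0)) + 1
    bonds = []
    for slot in range(n_water_slots):
        for name, el in (("O", "O"), ("H1", "H"), ("H2", "H")):
            q, s, e, m = wp[el]
            atoms.append(
                Atom(
                    index=idx,
                    name=name,
                    element=el,
                    residue_name="WAT",
                    residue_index=slot + 1,
                    molecule_id=mol,
                    charge=q,
                    lj_sigma=s,
                    lj_epsilon=e,
                    mass=m,
                    role="water",
                )
            )
            idx += 1
        bonds += [(idx - 3, idx - 2), (idx - 3, idx - 1)]
        mol += 1
    for slot in range(n_cosolute_slots):
        first = idx
        for name, el, q, s, e, m in COSOLUTE_SITES:
            if water_params == "zero":
                q, s, e = 0.0, 0.0, 0.0
            atoms.append(
                Atom(
                    index=idx,
                    name=name,
                    element=el,
                    residue_name="EGT",
                    residue_index=slot + 1,
                    molecule_id=mol,
                    charge=q,
                    lj_sigma=s,
                    lj_epsilon=e,
                    mass=m,
                    role="cosolute",
                )
            )
            idx += 1
        bonds.append((first, first + 1))
        mol += 1
    return Topology(atoms, bonds)


# ---------------------------------------------------------------------------
# Toy solutes
# ---------------------------------------------------------------------------

_BASE_G = ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4")
_BASE_T = ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6")
_SUGAR = ("C5'", "C4'", "O4'", "C3'", "C2'", "C1'", "O3'")
_PHOS = ("P", "OP1", "OP2", "O5'")

_TOY_CHARGES = {
    "P": 1.0,
    "OP1": -0.8,
    "OP2": -0.8,
    "O5'": -0.2,
    "O3'": -0.2,
    "C1'": 0.1,
}


def make_toy_system(
    kind: str,
    charge: float = 0.0,
    length: float = 30.0,
    spacing: float = 1.5,
) -> tuple[Topology, Frame]:
    """Deterministic toy solutes.

    * ``sphere`` — a single atom at the origin carrying ``charge``.
    * ``rod`` — collinear atoms along z spaced ``spacing`` Å over ``length``.
    * ``dinucleotide`` — a two-residue G/T toy strand whose atom names carry
      base / sugar / phosphate-group classes (one phosphodiester linkage,
      stated arbitrary charges with formal net -1 e).
    """
    if kind == "sphere":
        atoms = [
            Atom(0, "S1", "C", "TOY", 1, 0, charge=charge, lj_sigma=3.4,
                 lj_epsilon=0.1, mass=12.011)
        ]
        coords = np.zeros((1, 3))
        return Topology(atoms), Frame(coords)
    if kind == "rod":
        n = int(round(length / spacing)) + 1
        atoms = [
            Atom(i, "C" if i else "S1", "C", "TOY", 1, 0, charge=charge / n,
                 lj_sigma=3.4, lj_epsilon=0.1, mass=12.011)
            for i in range(n)
        ]
        coords = np.column_stack(
            [np.zeros(n), np.zeros(n), spacing * np.arange(n)]
        )
        return Topology(atoms), Frame(coords)
    if kind == "dinucleotide":
        atoms = []
        coords = []
        idx = 0
        for resseq, resname, names in (
            (1, "DG", _SUGAR + _BASE_G),
            (2, "DT", _PHOS + _SUGAR + _BASE_T),
        ):
            for j, name in enumerate(names):
                el = name.strip("'")[0]
                atoms.append(
                    Atom(
                        index=idx,
                        name=name,
                        element=el,
                        residue_name=resname,
                        residue_index=resseq,
                        molecule_id=0,
                        charge=_TOY_CHARGES.get(name, 0.0),
                        lj_sigma=3.2,
                        lj_epsilon=0.1,
                        mass=14.0,
                        role="solute",
                    )
                )
                # deterministic loose helix; geometry is schematic
                t = 0.9 * j
                coords.append(
                    [2.2 * math.cos(t), 2.2 * math.sin(t), 0.35 * j + 4.5 * (resseq - 1)]
                )
                idx += 1
        return Topology(atoms), Frame(np.array(coords))
    raise ValueError(f"unknown toy kind {kind!r}")


# ---------------------------------------------------------------------------
# Uniform (bulk) ensemble
# ---------------------------------------------------------------------------


def gen_uniform_solvent_frames(
    density: float,
    box,
    n_frames: int,
    seed,
    water_params: str = "tip3p",
) -> Trajectory:
    """Ideal-gas water ensemble at a target bulk density.

    Per frame the water count is Poisson(density * volume), positions are
    uniform in the box and orientations Haar-uniform. Deterministic given
    the seed. The topology carries ``max`` slots; frames mark absent slots
    inactive.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    volume = float(np.prod(box))
    if density * volume < 1:
        raise GeneratorError("expected molecule count below 1; enlarge the box")
    rng = _rng(seed)
    counts = rng.poisson(density * volume, size=n_frames)
    n_slots = int(counts.max())
    frames_data = []
    for k in counts:
        pos = rng.uniform(0.0, box, size=(int(k), 3))
        quats = gen_orientation_samples(int(k), kappa=0.0, seed=rng) if k else np.zeros((0, 4))
        frames_data.append(water_site_coords(pos, quats) if k else np.zeros((0, 3, 3)))
    topology = _build_topology([], n_slots, water_params=water_params)
    frames = []
    for sites in frames_data:
        k = sites.shape[0]
        coords = np.full((3 * n_slots, 3), np.nan)
        coords[: 3 * k] = sites.reshape(-1, 3)
        active = np.zeros(3 * n_slots, dtype=bool)
        active[: 3 * k] = True
        frames.append(
            Frame(coords, box=box, active=None if k == n_slots else active)
        )
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# Shell-structured ensemble
# ---------------------------------------------------------------------------


@dataclass
class ShellModelSpec:
    """Specification of a radially structured hydration ensemble.

    ``g_shells`` / ``kappa_shells`` / ``cosolute_shells`` are lists of
    ``(lo, hi, value)`` pieces over r_min (Å); outside all pieces g defaults
    to ``g_outside``, the orientation concentration to 0 (Haar) and the
    cosolute fraction to 0.
    """

    solute_kind: str = "sphere"
    solute_charge: float = 0.0
    box: tuple = (24.0, 24.0, 24.0)
    rho0: float = RHO0_BULK
    g_shells: list = field(default_factory=lambda: [(0.0, 2.0, 0.0), (2.0, 4.0, 2.0)])
    g_outside: float = 1.0
    kappa_shells: list = field(default_factory=list)
    cosolute_shells: list = field(default_factory=list)
    n_frames: int = 100
    seed: int = 0
    spacing: float = 0.5
    water_params: str = "tip3p"

    def g_of(self, r: np.ndarray) -> np.ndarray:
        return _piecewise(r, self.g_shells, self.g_outside)

    def kappa_of(self, r: np.ndarray) -> np.ndarray:
        return _piecewise(r, self.kappa_shells, 0.0)

    def cosolute_fraction_of(self, r: np.ndarray) -> np.ndarray:
        return _piecewise(r, self.cosolute_shells, 0.0)


def _piecewise(r: np.ndarray, pieces, outside: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, float(outside))
    for lo, hi, val in pieces:
        out[(r >= lo) & (r < hi)] = float(val)
    return out


def generator_grid(spec: ShellModelSpec) -> Grid:
    """The grid the generator discretizes its profile on (covers the box)."""
    box = np.asarray(spec.box, dtype=float)
    if np.any(np.abs(np.round(box / spec.spacing) * spec.spacing - box) > 1e-9):
        raise GeneratorError("box lengths must be multiples of the grid spacing")
    return build_grid((0.0, 0.0, 0.0), tuple(box), spec.spacing)


def gen_shell_solvent_frames(spec: ShellModelSpec):
    """Generate a shell-structured ensemble.

    Returns ``(trajectory, info)`` where ``info`` carries the solute frame,
    the generator grid and the ground-truth per-voxel expectations for
    recovery tests.
    """
    grid = generator_grid(spec)
    solute_top, solute_frame = make_toy_system(spec.solute_kind, charge=spec.solute_charge)
    center = np.asarray(spec.box) / 2.0
    solute_coords = (
        solute_frame.coordinates
        - solute_frame.coordinates.mean(axis=0)
        + center
    )
    from scipy.spatial import cKDTree

    centers = grid.centers()
    r_min, _ = cKDTree(solute_coords).query(centers)
    g_vox = spec.g_of(r_min)
    if np.any(g_vox < 0):
        raise GeneratorError("g must be non-negative")
    lam = g_vox * spec.rho0 * grid.voxel_volume
    if np.any(g_vox * spec.rho0 > 0.2):
        raise GeneratorError("target density exceeds a packable water density")
    kappa_vox = spec.kappa_of(r_min)
    cosol_vox = spec.cosolute_fraction_of(r_min)

    rng = _rng(spec.seed)
    nx, ny, nz = grid.dims
    ijk_all = np.stack(np.unravel_index(np.arange(grid.n_voxels), grid.dims), axis=1)
    origin = np.asarray(grid.origin)

    per_frame = []  # (water_sites, cosolute_sites)
    max_w = 1
    max_c = 0
    exclusion_tree = cKDTree(solute_coords)
    for _ in range(spec.n_frames):
        counts = rng.poisson(lam)
        occupied = np.flatnonzero(counts)
        reps = counts[occupied]
        vox_rep = np.repeat(occupied, reps)
        lo_corner = origin + ijk_all[vox_rep] * grid.spacing
        pos = lo_corner + rng.uniform(size=(vox_rep.size, 3)) * grid.spacing
        # species split by shell-dependent cosolute fraction
        frac = cosol_vox[vox_rep]
        is_cos = rng.uniform(size=vox_rep.size) < frac
        # waters
        wpos = pos[~is_cos]
        kap = kappa_vox[vox_rep][~is_cos]
        quats = np.empty((wpos.shape[0], 4))
        for kv in np.unique(kap):
            sel = kap == kv
            quats[sel] = gen_orientation_samples(int(sel.sum()), kappa=float(kv), seed=rng)
        wsites = water_site_coords(wpos, quats)
        # cosolutes: random orientation of the two-site rigid body,
        # hard-core exclusion against the solute
        cpos = pos[is_cos]
        if cpos.size:
            axis = rng.normal(size=(cpos.shape[0], 3))
            axis /= np.linalg.norm(axis, axis=1, keepdims=True)
            second = cpos + COSOLUTE_BOND_LENGTH * axis
            csites = np.stack([cpos, second], axis=1)
            dmin, _ = exclusion_tree.query(csites.reshape(-1, 3))
            ok = dmin.reshape(-1, 2).min(axis=1) > 1.2
            csites = csites[ok]
        else:
            csites = np.zeros((0, 2, 3))
        per_frame.append((wsites, csites))
        max_w = max(max_w, wsites.shape[0])
        max_c = max(max_c, csites.shape[0])

    solute_atoms = list(solute_top.atoms())
    topology = _build_topology(
        solute_atoms, max_w, max_c, water_params=spec.water_params
    )
    ns = len(solute_atoms)
    n_atoms = ns + 3 * max_w + 2 * max_c
    frames = []
    box = np.asarray(spec.box, dtype=float)
    for wsites, csites in per_frame:
        coords = np.full((n_atoms, 3), np.nan)
        active = np.zeros(n_atoms, dtype=bool)
        coords[:ns] = solute_coords
        active[:ns] = True
        kw = wsites.shape[0]
        coords[ns : ns + 3 * kw] = wsites.reshape(-1, 3)
        active[ns : ns + 3 * kw] = True
        kc = csites.shape[0]
        c0 = ns + 3 * max_w
        coords[c0 : c0 + 2 * kc] = csites.reshape(-1, 3)
        active[c0 : c0 + 2 * kc] = True
        frames.append(Frame(coords, box=box, active=None if active.all() else active))
    trajectory = Trajectory(topology, frames)
    info = {
        "grid": grid,
        "solute_coords": solute_coords,
        "r_min": r_min,
        "expected_occupancy": lam,
        "g_vox": g_vox,
        "spec": spec,
    }
    return trajectory, info


def write_manifest(spec: ShellModelSpec, path) -> None:
    """Record the generator ground truth for recovery tests."""
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


@dataclass
class OracleResult:
    """Independent slow-path totals for engine cross-checks."""

    e_sw_total: float  # mean per-frame water-solute energy, kcal/mol
    e_ww_total: float  # mean per-frame water-water energy, kcal/mol
    occupancy: np.ndarray  # mean water count per voxel


def _pair_e(ci, cj, qi, qj, si, sj, ei, ej, box):
    d = [ci[a] - cj[a] for a in range(3)]
    if box is not None:
        d = [d[a] - box[a] * round(d[a] / box[a]) for a in range(3)]
    r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    e = COULOMB_K * qi * qj / r
    eps = math.sqrt(ei * ej)
    if eps > 0:
        sr6 = ((si + sj) / 2.0 / r) ** 6
        e += 4.0 * eps * (sr6 * sr6 - sr6)
    return e


def oracle_direct(trajectory: Trajectory, grid: Grid) -> OracleResult:
    """O(N²) pair-energy totals and a direct occupancy histogram.

    Deliberately slow scalar arithmetic, independent of the vectorized
    engine; intended for small systems only.
    """
    top = trajectory.topology
    trip = top.water_triplets()
    other = np.flatnonzero(top.roles != "water")
    occ = np.zeros(grid.n_voxels)
    tot_sw = 0.0
    tot_ww = 0.0
    for frame in trajectory:
        mask = frame.active_mask()
        coords = frame.coordinates
        box = frame.box
        live = [t for t in trip if mask[t[0]]]
        live_other = [i for i in other if mask[i]]
        for t in live:
            o = coords[t[0]]
            ijk = []
            ok = True
            for a in range(3):
                v = int(math.floor((o[a] - grid.origin[a]) / grid.spacing))
                if not 0 <= v < grid.dims[a]:
                    ok = False
                    break
                ijk.append(v)
            if ok:
                occ[(ijk[0] * grid.dims[1] + ijk[1]) * grid.dims[2] + ijk[2]] += 1
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                for i in live[a]:
                    for j in live[b]:
                        tot_ww += _pair_e(
                            coords[i], coords[j],
                            top.charges[i], top.charges[j],
                            top.lj_sigma[i], top.lj_sigma[j],
                            top.lj_epsilon[i], top.lj_epsilon[j],
                            box,
                        )
        for t in live:
            for i in t:
                for j in live_other:
                    tot_sw += _pair_e(
                        coords[i], coords[j],
                        top.charges[i], top.charges[j],
                        top.lj_sigma[i], top.lj_sigma[j],
                        top.lj_epsilon[i], top.lj_epsilon[j],
                        box,
                    )
    nf = trajectory.frame_count
    return OracleResult(
        e_sw_total=tot_sw / nf, e_ww_total=tot_ww / nf, occupancy=occ / nf
    )


def mc_sasa(
    atom_coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    n_samples_per_atom: int = 4000,
    seed: int = 0,
) -> float:
    """Monte-Carlo SASA: random points on each expanded sphere, keep the
    fraction outside every other expanded sphere. Independent of the
    deterministic-lattice implementation."""
    rng = _rng(seed)
    atoms = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (atoms.shape[0],))
    expanded = radii + probe_radius
    total = 0.0
    for i in range(atoms.shape[0]):
        v = rng.normal(size=(n_samples_per_atom, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = atoms[i] + expanded[i] * v
        buried = np.zeros(n_samples_per_atom, dtype=bool)
        for j in range(atoms.shape[0]):
            if j == i:
                continue
            buried |= (
                np.linalg.norm(pts - atoms[j], axis=1) < expanded[j] - 1e-9
            )
        total += (1.0 - buried.mean()) * 4.0 * np.pi * expanded[i] ** 2
    return float(total)
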