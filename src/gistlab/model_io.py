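"""Structures, force-field parameters and solvent frame ensembles.

The on-disk trajectory format is multi-model PDB (ATOM/HETATM, MODEL/ENDMDL,
CRYST1 for the orthorhombic box). Models may differ in their solvent content:
synthetic grand-canonical-style ensembles have a fluctuating number of water
(and cosolute) molecules per frame, so the topology describes the union of
all atom slots and each :class:`Frame` carries an active-slot mask. Atom
serial numbers identify slots across models.

Per-atom force-field parameters (partial charge, Lennard-Jones sigma/epsilon,
mass) come from a plain-text sidecar table keyed by (residue name, atom name).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    EmptySystemError,
    MissingParameterError,
    ParseError,
    SelectionError,
    StructureError,
)

ROLES = ("solute", "water", "cosolute", "ion")

#: Residue-name -> role mapping used when loading structures. Configurable:
#: pass ``role_map`` to :func:`load_structure` to override or extend.
DEFAULT_ROLE_MAP = {
    "water": {"HOH", "WAT", "TIP3", "SOL", "SPC"},
    "ion": {"K", "K+", "NA", "NA+", "CL", "CL-", "MG", "KCL"},
    "cosolute": {"EG", "EGT", "EGL", "EDO"},
}

#: Atom names forming the phosphate group of a nucleotide backbone
#: (P, the two non-bridging oxygens under either naming convention, and the
#: two bridging esters O5'/O3').
PHOSPHATE_ATOMS = {"P", "OP1", "O1P", "OP2", "O2P", "O5'", "O3'", "O5*", "O3*"}

_SUGAR_MARKS = ("'", "*")

#: Packaged default rigid 3-site water parameters (TIP3P):
#: (charge e, sigma Å, epsilon kcal/mol, mass amu).
DEFAULT_WATER_PARAMS = {
    "O": (-0.834, 3.15061, 0.1521, 15.9994),
    "H": (0.417, 0.0, 0.0, 1.008),
}


@dataclass
class Atom:
    """One atom of the system; units: e, Å, kcal/mol, amu."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    molecule_id: int
    charge: float = np.nan
    lj_sigma: float = np.nan
    lj_epsilon: float = np.nan
    mass: float = np.nan
    role: str = "solute"


class Topology:
    """Column-oriented atom table plus bonds.

    Atom indices are contiguous 0..n-1. ``molecule_id`` groups the atoms of a
    molecule (each water/cosolute/ion residue is one molecule; the whole
    solute is molecule 0).
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Iterable[tuple[int, int]] = ()):
        atoms = list(atoms)
        if [a.index for a in atoms] != list(range(len(atoms))):
            raise ValueError("atom indices must be contiguous 0..n-1")
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_indices = np.array([a.residue_index for a in atoms], dtype=int)
        self.molecule_ids = np.array([a.molecule_id for a in atoms], dtype=int)
        self.charges = np.array([a.charge for a in atoms], dtype=float)
        self.lj_sigma = np.array([a.lj_sigma for a in atoms], dtype=float)
        self.lj_epsilon = np.array([a.lj_epsilon for a in atoms], dtype=float)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.roles = np.array([a.role for a in atoms], dtype=object)
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if np.any(np.nan_to_num(self.lj_sigma, nan=0.0) < 0) or np.any(
            np.nan_to_num(self.lj_epsilon, nan=0.0) < 0
        ):
            raise ValueError("Lennard-Jones sigma/epsilon must be >= 0")
        self.bonds = sorted({tuple(sorted(b)) for b in bonds})

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> Atom:
        return Atom(
            index=i,
            name=self.names[i],
            element=self.elements[i],
            residue_name=self.residue_names[i],
            residue_index=int(self.residue_indices[i]),
            molecule_id=int(self.molecule_ids[i]),
            charge=float(self.charges[i]),
            lj_sigma=float(self.lj_sigma[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            mass=float(self.masses[i]),
            role=self.roles[i],
        )

    def atoms(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(self.n_atoms))

    # -- species helpers -------------------------------------------------

    def indices_of_role(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise SelectionError(f"unknown role {role!r}")
        return np.flatnonzero(self.roles == role)

    def water_triplets(self) -> np.ndarray:
        """(n_waters, 3) array of [O, H, H] atom indices per water molecule.

        Raises :class:`StructureError` if any water molecule is not exactly
        one oxygen plus two hydrogens.
        """
        widx = self.indices_of_role("water")
        trip = []
        for mol in np.unique(self.molecule_ids[widx]):
            members = widx[self.molecule_ids[widx] == mol]
            ox = [i for i in members if self.elements[i] == "O"]
            hy = [i for i in members if self.elements[i] == "H"]
            if len(ox) != 1 or len(hy) != 2 or len(members) != 3:
                raise StructureError(
                    f"water molecule {mol} is not a rigid 3-site water "
                    f"(atoms {[self.names[i] for i in members]})"
                )
            trip.append([ox[0], hy[0], hy[1]])
        return np.array(trip, dtype=int).reshape(-1, 3)

    def molecule_members(self, role: str) -> list[np.ndarray]:
        """Atom-index arrays per molecule of the given role, sorted by id."""
        idx = self.indices_of_role(role)
        return [
            idx[self.molecule_ids[idx] == mol]
            for mol in np.unique(self.molecule_ids[idx])
        ]

    def subset(self, keep: np.ndarray) -> "Topology":
        keep = np.asarray(sorted(keep), dtype=int)
        remap = {int(old): new for new, old in enumerate(keep)}
        atoms = []
        for new, old in enumerate(keep):
            a = self.atom(int(old))
            a.index = new
            atoms.append(a)
        bonds = [
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in remap and j in remap
        ]
        return Topology(atoms, bonds)

    def with_water_bonds(self) -> "Topology":
        """Return a copy with O-H bonds added for every water molecule."""
        bonds = set(map(tuple, self.bonds))
        try:
            for o, h1, h2 in self.water_triplets():
                bonds.add(tuple(sorted((int(o), int(h1)))))
                bonds.add(tuple(sorted((int(o), int(h2)))))
        except StructureError:
            pass
        new = self.subset(np.arange(self.n_atoms))
        new.bonds = sorted(bonds)
        return new


@dataclass
class Frame:
    """Coordinates (Å) for every topology atom slot, plus the periodic box.

    ``active`` marks which slots are occupied this frame (None = all).
    Inactive slots hold NaN coordinates so accidental use fails loudly.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    active: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")
        if self.active is not None:
            self.active = np.asarray(self.active, dtype=bool).reshape(-1)
            if self.active.shape[0] != self.coordinates.shape[0]:
                raise ValueError("active mask length must equal atom count")

    def active_mask(self) -> np.ndarray:
        if self.active is None:
            return np.ones(self.coordinates.shape[0], dtype=bool)
        return self.active

    @property
    def n_active(self) -> int:
        return int(self.active_mask().sum())


@dataclass
class Trajectory:
    """An ordered ensemble of frames over one topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError("frame coordinate count != topology atom count")

    @property
    def frame_count(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def subset_frames(self, selector) -> "Trajectory":
        frames = [self.frames[i] for i in np.arange(self.frame_count)[selector]]
        return Trajectory(self.topology, frames)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _role_of(residue_name: str, role_map: dict) -> str:
    for role in ("water", "ion", "cosolute"):
        if residue_name in role_map.get(role, ()):
            return role
    return "solute"


def _infer_element(name: str, raw_element: str) -> str:
    el = raw_element.strip().upper()
    if el:
        return el[0] + el[1:].lower() if len(el) > 1 and el[1].isalpha() else el
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def load_structure(path, role_map: dict | None = None):
    """Read a (multi-model) PDB file.

    Returns ``(topology, trajectory)`` with one frame per MODEL (a single
    frame when no MODEL records are present). Roles are inferred from residue
    names via ``role_map`` (default :data:`DEFAULT_ROLE_MAP`); charges and
    Lennard-Jones parameters stay unset until
    :func:`load_forcefield_params`.
    """
    role_map = role_map or DEFAULT_ROLE_MAP
    models: list[dict] = []  # serial -> (record, xyz)
    box = None
    current: dict | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError as exc:
                    raise ParseError(f"bad CRYST1 record: {exc}", lineno)
            elif rec == "MODEL ":
                saw_model = True
                current = {}
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = {}
                    if not saw_model:
                        models.append(current)
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    altloc = line[16]
                    resname = line[17:21].strip()
                    resseq = int(line[22:26])
                    xyz = (
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                    )
                except ValueError as exc:
                    raise ParseError(f"malformed atom record: {exc}", lineno)
                if altloc not in (" ", "A"):
                    warnings.warn(
                        f"line {lineno}: skipping altloc {altloc!r} for atom {name}"
                    )
                    continue
                element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
                current[serial] = ((name, resname, resseq, element), np.array(xyz))
    if current is not None and current not in models:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"no atoms found in {path}")

    # Union topology over models, keyed by serial; slot order by serial.
    union: dict[int, tuple] = {}
    for m in models:
        for serial, (key, _) in m.items():
            if serial in union and union[serial] != key:
                raise ParseError(
                    f"atom serial {serial} is inconsistent across models"
                )
            union.setdefault(serial, key)
    serials = sorted(union)
    slot_of = {s: i for i, s in enumerate(serials)}

    atoms = []
    mol_id = 0
    prev_res = None
    for i, s in enumerate(serials):
        name, resname, resseq, element = union[s]
        role = _role_of(resname, role_map)
        if role != "solute":
            if prev_res != ("x", resname, resseq, role):
                mol_id += 1
            prev_res = ("x", resname, resseq, role)
            mid = mol_id
        else:
            mid = 0
            prev_res = None
        atoms.append(
            Atom(
                index=i,
                name=name,
                element=element,
                residue_name=resname,
                residue_index=resseq,
                molecule_id=mid,
                role=role,
            )
        )
    topology = Topology(atoms).with_water_bonds()

    frames = []
    n = len(serials)
    for m in models:
        coords = np.full((n, 3), np.nan)
        active = np.zeros(n, dtype=bool)
        for serial, (_, xyz) in m.items():
            slot = slot_of[serial]
            coords[slot] = xyz
            active[slot] = True
        frames.append(
            Frame(coords, box=box, active=None if active.all() else active)
        )
    return topology, Trajectory(topology, frames)


def write_structure(trajectory: Trajectory, path) -> None:
    """Write a multi-model PDB (CRYST1 from the first frame's box)."""
    top = trajectory.topology
    with open(path, "w") as fh:
        box = trajectory.frames[0].box
        if box is not None:
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        multi = trajectory.frame_count > 1
        for imodel, frame in enumerate(trajectory.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            mask = frame.active_mask()
            for i in range(top.n_atoms):
                if not mask[i]:
                    continue
                x, y, z = frame.coordinates[i]
                name = top.names[i]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name[:4]
                el = top.elements[i].upper()[:2]
                fh.write(
                    f"ATOM  {i + 1:5d} {pdb_name}{'':1s}{top.residue_names[i]:<4s}"
                    f"{'':1s}{top.residue_indices[i]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {el:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Force-field parameter sidecar
# ---------------------------------------------------------------------------


def load_forcefield_params(topology: Topology, path) -> Topology:
    """Assign per-atom parameters from a sidecar table.

    The sidecar is a whitespace- or comma-separated text table with columns
    ``residue atom charge sigma epsilon mass`` (units e, Å, kcal/mol, amu);
    ``#`` starts a comment. Water residues missing from the table fall back
    to the packaged default water set. Raises
    :class:`MissingParameterError` naming every unmapped atom.
    """
    table: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if parts[0].lower() == "residue":
                continue
            if len(parts) != 6:
                raise ParseError(
                    f"expected 6 columns (residue atom charge sigma epsilon mass), "
                    f"got {len(parts)}",
                    lineno,
                )
            try:
                vals = tuple(float(v) for v in parts[2:])
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
            table[(parts[0], parts[1])] = vals
    return assign_params(topology, table)


def assign_params(topology: Topology, table: dict) -> Topology:
    """Apply a ``(residue, atom) -> (q, sigma, eps, mass)`` mapping."""
    new = topology.subset(np.arange(topology.n_atoms))
    new.bonds = list(topology.bonds)
    missing = []
    for i in range(new.n_atoms):
        key = (new.residue_names[i], new.names[i])
        vals = table.get(key)
        if vals is None and new.roles[i] == "water":
            vals = DEFAULT_WATER_PARAMS.get(new.elements[i])
        if vals is None:
            missing.append(f"{key[0]}/{key[1]}")
            continue
        new.charges[i], new.lj_sigma[i], new.lj_epsilon[i], new.masses[i] = vals
    if missing:
        raise MissingParameterError(
            "no parameters for atoms: " + ", ".join(sorted(set(missing)))
        )
    return new


def apply_default_water_params(topology: Topology) -> Topology:
    """Assign the packaged default water set (other atoms untouched)."""
    new = topology.subset(np.arange(topology.n_atoms))
    new.bonds = list(topology.bonds)
    for i in np.flatnonzero(new.roles == "water"):
        vals = DEFAULT_WATER_PARAMS.get(new.elements[i])
        if vals is None:
            raise StructureError(f"water atom {new.names[i]} is not O or H")
        new.charges[i], new.lj_sigma[i], new.lj_epsilon[i], new.masses[i] = vals
    return new


def write_forcefield_params(topology: Topology, path) -> None:
    """Write the sidecar table for every distinct (residue, atom) pair."""
    seen = {}
    for i in range(topology.n_atoms):
        key = (topology.residue_names[i], topology.names[i])
        seen.setdefault(
            key,
            (
                topology.charges[i],
                topology.lj_sigma[i],
                topology.lj_epsilon[i],
                topology.masses[i],
            ),
        )
    with open(path, "w") as fh:
        fh.write("# residue atom charge(e) sigma(A) epsilon(kcal/mol) mass(amu)\n")
        for (res, name), (q, s, e, m) in sorted(seen.items()):
            fh.write(f"{res:<6s} {name:<6s} {q: .6f} {s: .6f} {e: .6f} {m: .6f}\n")


# ---------------------------------------------------------------------------
# Selections and species stripping
# ---------------------------------------------------------------------------

ATOM_CLASSES = ("all", "base", "phosphate-group")


def _is_phosphate(name: str) -> bool:
    return name in PHOSPHATE_ATOMS


def _is_base(name: str) -> bool:
    if any(m in name for m in _SUGAR_MARKS):
        return False
    return not _is_phosphate(name)


def select_atoms(
    topology: Topology,
    role: str | None = None,
    residue_indices: Iterable[int] | None = None,
    residue_names: Iterable[str] | None = None,
    atom_class: str = "all",
    allow_empty: bool = False,
) -> set[int]:
    """Deterministic atom-index selection.

    Criteria combine by intersection: role, residue index/name, and an
    atom-name class (``all``, ``base``, or ``phosphate-group``; the latter is
    P, OP1/O1P, OP2/O2P, O5', O3'). The base class is every non-sugar,
    non-phosphate atom of the residue, i.e. the nucleobase and its hydrogens.
    """
    if atom_class not in ATOM_CLASSES:
        raise SelectionError(f"unknown atom class {atom_class!r}")
    mask = np.ones(topology.n_atoms, dtype=bool)
    if role is not None:
        if role not in ROLES:
            raise SelectionError(f"unknown role {role!r}")
        mask &= topology.roles == role
    if residue_indices is not None:
        wanted = set(int(r) for r in residue_indices)
        mask &= np.array([int(r) in wanted for r in topology.residue_indices])
    if residue_names is not None:
        wanted_names = set(residue_names)
        mask &= np.array([r in wanted_names for r in topology.residue_names])
    if atom_class == "base":
        mask &= np.array([_is_base(n) for n in topology.names])
    elif atom_class == "phosphate-group":
        mask &= np.array([_is_phosphate(n) for n in topology.names])
    out = set(map(int, np.flatnonzero(mask)))
    if not out and not allow_empty:
        raise SelectionError("selection matched no atoms")
    return out


def strip_species(trajectory: Trajectory, roles_to_remove: Iterable[str]) -> Trajectory:
    """Remove all atoms of the given roles from every frame.

    Frame count and the coordinates of the remaining atoms are unchanged.
    """
    roles_to_remove = set(roles_to_remove)
    bad = roles_to_remove - set(ROLES)
    if bad:
        raise SelectionError(f"unknown roles: {sorted(bad)}")
    top = trajectory.topology
    keep = np.flatnonzero(~np.isin(top.roles, list(roles_to_remove)))
    if keep.size == 0:
        raise EmptySystemError("stripping would remove every atom")
    new_top = top.subset(keep)
    frames = []
    for f in trajectory.frames:
        active = f.active[keep] if f.active is not None else None
        if active is not None and active.all():
            active = None
        frames.append(Frame(f.coordinates[keep], box=f.box, active=active))
    return Trajectory(new_top, frames)
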