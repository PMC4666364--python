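"""Shared fixtures: toy solutes and hand-built water trajectories."""

import numpy as np
import pytest

from gistlab.model_io import Frame, Topology, Trajectory
from gistlab.synthetic import (
    _build_topology,
    make_toy_system,
    water_site_coords,
)


@pytest.fixture
def dinucleotide():
    """Two-residue G/T toy strand with base/phosphate atom classes."""
    return make_toy_system("dinucleotide")


def build_water_trajectory(
    o_positions_per_frame,
    quats_per_frame=None,
    box=None,
    water_params="tip3p",
    solute=None,
):
    """Trajectory with explicitly placed rigid waters (fixed count).

    ``o_positions_per_frame``: list of (n, 3) oxygen positions, equal n.
    ``quats_per_frame``: matching orientation quaternions (default identity).
    ``solute``: optional (Topology, Frame) toy prepended with static coords.
    """
    n = len(o_positions_per_frame[0])
    sol_atoms, sol_coords = [], np.zeros((0, 3))
    if solute is not None:
        sol_top, sol_frame = solute
        sol_atoms = list(sol_top.atoms())
        sol_coords = sol_frame.coordinates
    top = _build_topology(sol_atoms, n, water_params=water_params)
    frames = []
    for fi, opos in enumerate(o_positions_per_frame):
        opos = np.asarray(opos, dtype=float).reshape(-1, 3)
        if quats_per_frame is None:
            q = np.tile([0.0, 0.0, 0.0, 1.0], (opos.shape[0], 1))
        else:
            q = np.asarray(quats_per_frame[fi], dtype=float).reshape(-1, 4)
        sites = water_site_coords(opos, q).reshape(-1, 3)
        coords = np.vstack([sol_coords, sites])
        frames.append(Frame(coords, box=box))
    return Trajectory(top, frames)


@pytest.fixture
def single_water_pdb(tmp_path):
    """Minimal one-model, one-water PDB file."""
    text = (
        "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1           1\n"
        "ATOM      1  O   WAT     1       5.000   5.000   5.000  1.00  0.00           O\n"
        "ATOM      2  H1  WAT     1       5.757   5.000   5.586  1.00  0.00           H\n"
        "ATOM      3  H2  WAT     1       4.243   5.000   5.586  1.00  0.00           H\n"
        "END\n"
    )
    p = tmp_path / "water.pdb"
    p.write_text(text)
    return p
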