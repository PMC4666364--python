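"""Config-driven end-to-end runs.

One run: read (or receive) a solvated trajectory, strip ions/cosolutes for
the voxel-thermodynamics stage (density profiles and hydrogen-bond counts
see the full system), build the grid around the solute, compute the
VoxelMap, aggregate the first-hydration-shell region, produce density
profiles and structural metrics, run a frame-subset convergence scan, and
write OpenDX maps, CSV tables, a JSON summary and a log. Outputs are
bit-reproducible given config + seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import GistLabError
from .gist import (
    BulkReference,
    accumulate_voxel_stats,
    grid_around,
    orient_entropy_map,
    trans_entropy_map,
    voxel_energies,
    write_dx,
)
from .metrics import HBondCriteria, count_hbonds, element_radii, rsasa_scan, shell_potential_profile
from .model_io import (
    Trajectory,
    load_forcefield_params,
    load_structure,
    apply_default_water_params,
    strip_species,
)
from .profiles import ProfileSpec, min_distance_density_profile, region_population_series
from .regions import (
    RegionSummary,
    region_from_rmin,
    region_summary,
    rmin_field,
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults follow the analysis
    conventions documented in docs/methods.md (0.5 Å voxels, 7 Å grid
    margin, 2–4 Å first shell, bulk rho0 = 0.0329 Å^-3,
    eps_ww0 = -9.565 kcal/mol, T = 298 K)."""

    trajectory: str = ""
    params: str | None = None
    output_dir: str = "gistlab_out"
    grid_spacing: float = 0.5
    grid_margin: float = 7.0
    region_lo: float = 2.0
    region_hi: float = 4.0
    rho0: float = 0.0329
    eps_ww0: float = -9.565
    temperature: float = 298.0
    delta_r: float = 0.5
    profile_r_max: float = 12.0
    hbond_max_distance: float = 3.5
    hbond_angle_lo: float = 135.0
    hbond_angle_hi: float = 180.0
    probe_radii: list = field(default_factory=lambda: [1.0, 1.4, 2.0, 2.4, 2.8, 3.2])
    sasa_reference_probe: float = 1.4
    frame_start: int = 0
    frame_stop: int | None = None
    frame_stride: int = 1
    min_orientation_samples: int = 10
    convergence_fractions: list = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    n_blocks: int = 5
    energy_cutoff: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def bulk(self) -> BulkReference:
        return BulkReference(
            rho0=self.rho0, eps_ww0=self.eps_ww0, temperature=self.temperature
        )


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc

    return _Ctx()


class _StageError(GistLabError):
    pass


def region_block_summaries(
    trajectory: Trajectory, grid, mask, bulk, n_blocks: int, cutoff=None, min_samples=10
) -> list[RegionSummary]:
    """Per-water summaries over non-overlapping frame blocks (SEM source)."""
    nf = trajectory.frame_count
    edges = np.linspace(0, nf, n_blocks + 1).astype(int)
    out = []
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        if edges[b + 1] - edges[b] < 1:
            continue
        sub = trajectory.subset_frames(sl)
        vm = accumulate_voxel_stats(sub, grid, bulk)
        vm = voxel_energies(sub, grid, cutoff=cutoff, voxelmap=vm)
        vm = trans_entropy_map(vm, bulk)
        vm = orient_entropy_map(vm, bulk, min_samples=min_samples)
        out.append(region_summary(vm, mask, bulk))
    return out


def run_pipeline(config: RunConfig, trajectory: Trajectory | None = None) -> dict:
    """Execute the full analysis; returns the output bundle (also on disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"gistlab {__version__} on {platform.python_version()}"]

    with _stage("load"):
        if trajectory is None:
            _, trajectory = load_structure(config.trajectory)
            if config.params:
                trajectory = Trajectory(
                    load_forcefield_params(trajectory.topology, config.params),
                    trajectory.frames,
                )
            else:
                trajectory = Trajectory(
                    apply_default_water_params(trajectory.topology),
                    trajectory.frames,
                )
        traj = trajectory.subset_frames(
            slice(config.frame_start, config.frame_stop, config.frame_stride)
        )
        log_lines.append(f"frames analysed: {traj.frame_count}")

    bulk = config.bulk()
    with _stage("strip"):
        top = traj.topology
        to_strip = {r for r in ("ion", "cosolute") if (top.roles == r).any()}
        gist_traj = strip_species(traj, to_strip) if to_strip else traj
        log_lines.append(f"stripped for GIST stage: {sorted(to_strip) or 'nothing'}")

    with _stage("grid"):
        solute_idx = np.flatnonzero(gist_traj.topology.roles == "solute")
        if solute_idx.size == 0:
            raise GistLabError("no solute atoms; cannot define the analysis grid")
        solute_coords = gist_traj.frames[0].coordinates[solute_idx]
        grid = grid_around(solute_coords, config.grid_margin, config.grid_spacing)
        field_ = rmin_field(grid, solute_coords)

    with _stage("gist"):
        vm = accumulate_voxel_stats(gist_traj, grid, bulk)
        vm = voxel_energies(gist_traj, grid, cutoff=config.energy_cutoff, voxelmap=vm)
        vm = trans_entropy_map(vm, bulk)
        vm = orient_entropy_map(vm, bulk, min_samples=config.min_orientation_samples)
        vm.write_csv(outdir / "gist_voxels.csv")
        for qty in ("n", "g", "E_sw", "E_ww", "TdS_tr", "TdS_or"):
            write_dx(grid, getattr(vm, qty), outdir / f"gist_{qty}.dx", name=qty)

    with _stage("regions"):
        mask = region_from_rmin(field_, config.region_lo, config.region_hi)
        summary = region_summary(vm, mask, bulk)
        blocks = region_block_summaries(
            gist_traj, grid, mask, bulk, config.n_blocks,
            cutoff=config.energy_cutoff, min_samples=config.min_orientation_samples,
        )
        with open(outdir / "region_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)

    with _stage("profiles"):
        profiles = {}
        for species in ("water", "cosolute"):
            if not (traj.topology.roles == species).any() and species != "water":
                continue
            spec = ProfileSpec(
                species=species,
                delta_r=config.delta_r,
                r_max=config.profile_r_max,
                rho0=config.rho0,
            )
            ptab = min_distance_density_profile(traj, field_, spec)
            ptab.write_csv(outdir / f"profile_{species}.csv")
            profiles[species] = ptab
        population = region_population_series(traj, mask, "water")
        np.savetxt(outdir / "region_population.csv", population, fmt="%d")

    with _stage("convergence"):
        rows = []
        for frac in config.convergence_fractions:
            nf = max(2, int(round(frac * gist_traj.frame_count)))
            sub = gist_traj.subset_frames(slice(0, nf))
            bsum = region_block_summaries(
                sub, grid, mask, bulk, config.n_blocks,
                cutoff=config.energy_cutoff,
                min_samples=config.min_orientation_samples,
            )
            vals = {
                f: np.mean([getattr(b, f) for b in bsum])
                for f in ("tds_tr_w", "tds_or_w", "de_sw_w", "de_ww_w", "dg_w")
            }
            sems = {
                f + "_sem": np.std([getattr(b, f) for b in bsum], ddof=1)
                / np.sqrt(len(bsum))
                for f in ("tds_tr_w", "tds_or_w", "de_sw_w", "de_ww_w", "dg_w")
            }
            rows.append({"frames": nf, **vals, **sems})
        import pandas as pd

        conv = pd.DataFrame(rows)
        conv.to_csv(outdir / "convergence.csv", index=False)

    with _stage("metrics"):
        radii = element_radii(gist_traj.topology, solute_idx)
        scan = rsasa_scan(
            solute_coords, radii, config.probe_radii, r0=config.sasa_reference_probe
        )
        scan.to_dataframe().to_csv(outdir / "sasa_scan.csv", index=False)
        metrics_out = {"sasa": scan}
        charges = gist_traj.topology.charges[solute_idx]
        if np.any(np.nan_to_num(charges) != 0):
            pot = shell_potential_profile(
                gist_traj.topology,
                gist_traj.frames[0],
                [2.0, 3.0, 4.0, 6.0, 8.0],
                atom_indices=solute_idx,
            )
            pot.to_dataframe().to_csv(outdir / "shell_potential.csv", index=False)
            metrics_out["potential"] = pot
        criteria = HBondCriteria(
            max_heavy_distance=config.hbond_max_distance,
            angle_lo=config.hbond_angle_lo,
            angle_hi=config.hbond_angle_hi,
        )
        hb_counts = []
        for frame in traj:
            rep = count_hbonds(
                frame,
                traj.topology,
                set(map(int, np.flatnonzero(traj.topology.roles == "solute"))),
                partner_role="water",
                criteria=criteria,
                partner_region=mask,
            )
            hb_counts.append(rep.normalized)
        hbonds = {
            "mean_normalized_solute_water": float(np.mean(hb_counts)),
            "frames": len(hb_counts),
        }
        with open(outdir / "hbonds.json", "w") as fh:
            json.dump(hbonds, fh, indent=2)
        metrics_out["hbonds"] = hbonds

    with _stage("manifest"):
        config.to_yaml(outdir / "config.yaml")
        manifest = {
            "gistlab_version": __version__,
            "seed": config.seed,
            "frames": traj.frame_count,
            "grid": {
                "origin": list(map(float, grid.origin)),
                "spacing": grid.spacing,
                "dims": list(grid.dims),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "grid": grid,
        "voxelmap": vm,
        "region_mask": mask,
        "summary": summary,
        "block_summaries": blocks,
        "profiles": profiles,
        "population": population,
        "convergence": conv,
        "metrics": metrics_out,
        "output_dir": outdir,
    }
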