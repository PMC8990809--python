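"""Workflow drivers and tabular/JSON reporting.

These functions tie the library modules into the two end-to-end
workflows (docking post-analysis; trajectory contact analysis), writing
CSV/JSON artifacts plus a reproducibility log under a run directory.
Outputs are byte-reproducible for a fixed config and seed: fixed
filenames, fixed column orders, fixed float formatting, no timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import DockingConfig, summarize_docking
from .config import RunConfig, config_hash
from .io import read_pose_set, read_structure, read_trajectory, write_pose_set_pdb
from .structures import MembraneFrame, SymmetrySpec
from .trajectory import (
    cluster_binding_sites,
    density_map,
    dual_cutoff_events,
    residence_times,
    residue_occupancy,
)

__all__ = ["run_dock_workflow", "run_traj_workflow"]

_FLOAT_FMT = "%.6f"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _start_log(config: RunConfig, out: Path, workflow: str) -> list[str]:
    import MDAnalysis
    import scipy

    from . import __version__

    return [
        f"pipsites {__version__} | workflow: {workflow}",
        f"numpy {np.__version__} scipy {scipy.__version__} "
        f"pandas {pd.__version__} MDAnalysis {MDAnalysis.__version__}",
        f"seed: {config.seed}",
        f"config sha256[:16]: {config_hash(config)}",
        "config: " + json.dumps(config.to_dict(), sort_keys=True),
    ]


def _stage(log: list[str], name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.append(f"stage {name}: FAILED ({exc})")
                raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
            log.append(f"stage {name}: ok")
            return False

    return _Ctx()


def run_dock_workflow(config: RunConfig, model=None, poses=None):
    """Docking post-analysis: vectorize -> orientation filter -> wedge
    reduction -> centroid clustering -> contact identification -> report.

    ``model`` and ``poses`` may be passed in memory; otherwise they are
    read from the paths in ``config``.  Returns
    ``(summary, clusters, frequency_table)`` and writes summary.json,
    clusters.csv, contact_frequencies.csv and run.log (plus
    representatives.pdb when requested) under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    log = _start_log(config, out, "dock-cluster")

    with _stage(log, "read_structure"):
        if model is None:
            if not config.structure:
                raise ValueError("config.structure is required")
            model = read_structure(config.structure)
        if model.symmetry.order != config.symmetry_order:
            sym = SymmetrySpec.cyclic(model.chains[: config.symmetry_order]) \
                if len(model.chains) >= config.symmetry_order else model.symmetry
            model.symmetry = sym
    with _stage(log, "read_pose_set"):
        if poses is None:
            if not config.poses:
                raise ValueError("config.poses is required")
            poses = read_pose_set(config.poses, species=config.species)
        log.append(f"poses read: {len(poses)}")

    frame = MembraneFrame(
        midplane_z=config.midplane_z,
        intracellular_boundary_z=config.intracellular_boundary_z,
    )
    dock_cfg = DockingConfig(
        cluster_cutoff=config.cluster_cutoff,
        contact_cutoff=config.contact_cutoff,
        tolerance_deg=config.tolerance_deg,
        cluster_mode=config.cluster_mode,
        state_label=config.state_label,
    )
    with _stage(log, "summarize_docking"):
        summary, clusters, freq_table, accepted = summarize_docking(
            poses, model, frame, sym=model.symmetry, config=dock_cfg
        )
    if summary.n_accepted == 0:
        log.append("warning: no poses accepted by the orientation filter")

    with _stage(log, "write_outputs"):
        _write_json(summary.to_dict(), out / "summary.json")
        rows = []
        for cl in clusters:
            mc = cl.mean_centroids
            rows.append({
                "cluster_id": cl.cluster_id,
                "size": cl.size,
                "representative_pose_id": cl.representative_pose_id,
                "member_pose_ids": ";".join(str(p) for p in cl.member_pose_ids),
                "c1_x": mc[0, 0], "c1_y": mc[0, 1], "c1_z": mc[0, 2],
                "inositol_x": mc[1, 0], "inositol_y": mc[1, 1], "inositol_z": mc[1, 2],
                "phosphate_x": mc[2, 0], "phosphate_y": mc[2, 1], "phosphate_z": mc[2, 2],
                "n_contact_residues": len(cl.residue_union),
            })
        _write_csv(
            pd.DataFrame(rows, columns=[
                "cluster_id", "size", "representative_pose_id", "member_pose_ids",
                "c1_x", "c1_y", "c1_z", "inositol_x", "inositol_y", "inositol_z",
                "phosphate_x", "phosphate_y", "phosphate_z", "n_contact_residues",
            ]),
            out / "clusters.csv",
        )
        _write_csv(freq_table, out / "contact_frequencies.csv")
        if config.write_representatives and clusters:
            from .structures import rotate_about_z

            reps = []
            by_id = {vec.pose_id: (pose, vec) for pose, vec in accepted}
            for cl in clusters:
                pose, vec = by_id[cl.representative_pose_id]
                rotated = type(pose)(
                    pose_id=pose.pose_id,
                    species=pose.species,
                    atom_names=list(pose.atom_names),
                    elements=list(pose.elements),
                    coords=rotate_about_z(
                        pose.coords, vec.wedge_rotation_k, model.symmetry.order
                    ),
                )
                reps.append(rotated)
            write_pose_set_pdb(reps, out / "representatives.pdb")

    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary, clusters, freq_table


def run_traj_workflow(config: RunConfig, traj=None):
    """Trajectory contact analysis: events -> occupancy -> durations ->
    binding sites -> density map -> report.

    Returns ``(events, occupancy_table, sites)`` and writes events.csv,
    residue_occupancy.csv, residence_times.csv, sites.csv,
    singleton_residues.csv, density_map.txt/.json and run.log under
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    log = _start_log(config, out, "traj-occupancy")

    with _stage(log, "read_trajectory"):
        if traj is None:
            if not config.trajectory:
                raise ValueError("config.trajectory is required")
            if config.trajectory_topology:
                traj = read_trajectory(
                    config.trajectory_topology,
                    lipid_resnames=config.lipid_resnames,
                    trajectory_path=config.trajectory,
                    frame_stride_ps=config.frame_stride_ps,
                )
            else:
                traj = read_trajectory(
                    config.trajectory,
                    lipid_resnames=config.lipid_resnames,
                    frame_stride_ps=config.frame_stride_ps,
                )
        log.append(f"frames: {traj.n_frames}")

    with _stage(log, "dual_cutoff_events"):
        events = dual_cutoff_events(traj, r_on_nm=config.r_on_nm, r_off_nm=config.r_off_nm)
        log.append(f"events: {len(events)}")
    with _stage(log, "residue_occupancy"):
        occ = residue_occupancy(events, traj.n_frames)
    with _stage(log, "residence_times"):
        times = residence_times(events, frame_stride_ps=traj.frame_stride_ps)
    with _stage(log, "cluster_binding_sites"):
        sites, singletons = cluster_binding_sites(
            events, traj.n_frames, min_edge_pct=config.min_edge_pct
        )
        log.append(f"sites: {len(sites)} (+{len(singletons)} singleton residues)")
    with _stage(log, "density_map"):
        dmap = density_map(
            traj,
            grid_spacing=config.grid_spacing,
            leaflet=config.leaflet,
            midplane_z=config.midplane_z,
        )

    with _stage(log, "write_outputs"):
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "lipid_id": ev.lipid_id,
                        "chain_id": ev.residue[0],
                        "residue_number": ev.residue[1],
                        "start_frame": ev.start_frame,
                        "end_frame": ev.end_frame,
                        "duration_frames": ev.duration_frames,
                    }
                    for ev in events
                ],
                columns=["lipid_id", "chain_id", "residue_number",
                         "start_frame", "end_frame", "duration_frames"],
            ),
            out / "events.csv",
        )
        _write_csv(occ, out / "residue_occupancy.csv")
        _write_csv(times, out / "residence_times.csv")
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "site_id": s.site_id,
                        "occupancy_pct": s.occupancy_pct,
                        "n_residues": len(s.residues),
                        "residues": ";".join(
                            f"{c}:{r}" for c, r in sorted(s.residues)
                        ),
                    }
                    for s in sites
                ],
                columns=["site_id", "occupancy_pct", "n_residues", "residues"],
            ),
            out / "sites.csv",
        )
        _write_csv(
            pd.DataFrame(
                [{"chain_id": c, "residue_number": r} for c, r in singletons],
                columns=["chain_id", "residue_number"],
            ),
            out / "singleton_residues.csv",
        )
        dmap.save_text(out / "density_map.txt", out / "density_map.json")

    (out / "run.log").write_text("\n".join(log) + "\n")
    return events, occ, sites
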