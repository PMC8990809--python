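"""Dual-cutoff lipid-residue contacts on coarse-grained trajectories.

A contact between a lipid headgroup and a residue begins the first frame
the minimum bead-particle distance drops to the inner radius (0.5 nm by
default) and persists while it stays within the outer radius (0.8 nm);
the event ends the frame before the distance exceeds the outer radius.
Occupancy is the percentage of frames a residue (or binding site) is in
contact with at least one lipid.  Binding sites group residues by
commonality: residues simultaneously contacted by the same lipid molecule
in enough frames are connected, and connected components become sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import FrameSeries, ResidueId

__all__ = [
    "ContactEvent",
    "BindingSite",
    "DensityMap",
    "min_distance_series",
    "dual_cutoff_events",
    "residue_occupancy",
    "residence_times",
    "cluster_binding_sites",
    "site_occupancy",
    "density_map",
    "events_to_frame_mask",
]

NM_TO_ANGSTROM = 10.0


@dataclass(frozen=True)
class ContactEvent:
    """One contiguous lipid-residue contact interval, frames inclusive."""

    lipid_id: int
    residue: ResidueId
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame <= self.end_frame):
            raise ValueError(f"invalid event frames [{self.start_frame}, {self.end_frame}]")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class BindingSite:
    site_id: int
    residues: frozenset[ResidueId]
    occupancy_pct: float
    top_residue_occupancies: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must contain at least one residue")
        if not (0.0 <= self.occupancy_pct <= 100.0):
            raise ValueError("occupancy_pct out of [0, 100]")


def _group_slices(keys_seq) -> tuple[list, np.ndarray]:
    """Unique keys (order of appearance) and start offsets for reduceat.

    Keys must already be grouped contiguously (as FrameSeries guarantees).
    """
    keys: list = []
    starts: list[int] = []
    prev = object()
    for i, k in enumerate(keys_seq):
        if k != prev:
            if k in keys:
                raise ValueError("atom groups are not contiguous in the FrameSeries")
            keys.append(k)
            starts.append(i)
            prev = k
    return keys, np.asarray(starts, dtype=int)


def min_distance_series(traj: FrameSeries) -> tuple[np.ndarray, list[int], list[ResidueId]]:
    """Per-frame minimum distance between every lipid and every residue.

    Returns ``(d, lipid_ids, residue_ids)`` with ``d`` of shape
    (n_frames, n_lipids, n_residues) in angstroms: the minimum over all
    headgroup beads of the lipid and all particles of the residue.
    """
    res_keys = [
        (c, int(r))
        for c, r in zip(traj.protein_chain_ids, traj.protein_residue_numbers)
    ]
    residues, res_starts = _group_slices(res_keys)
    lipids, lip_starts = _group_slices(int(l) for l in traj.lipid_ids)

    F = traj.n_frames
    d = np.empty((F, len(lipids), len(residues)))
    for f in range(F):
        full = cdist(traj.bead_coords[f], traj.protein_coords[f])
        by_lip = np.minimum.reduceat(full, lip_starts, axis=0)
        d[f] = np.minimum.reduceat(by_lip, res_starts, axis=1)
    return d, [int(l) for l in lipids], [tuple(r) for r in residues]


def dual_cutoff_events(
    traj: FrameSeries,
    r_on_nm: float = 0.5,
    r_off_nm: float = 0.8,
) -> list[ContactEvent]:
    """Detect lipid-residue contact events with the dual-cutoff scheme.

    Cutoffs are given in nm (the CG convention); coordinates are angstrom
    internally.  For each (lipid, residue) pair a contact starts at the
    first frame with distance <= r_on, persists while <= r_off, and ends
    the frame before the distance exceeds r_off.  Setting r_on == r_off
    recovers a plain single-cutoff scheme.
    """
    if not (0 < r_on_nm <= r_off_nm):
        raise ValueError(f"require 0 < r_on <= r_off, got {r_on_nm}, {r_off_nm}")
    d, lipids, residues = min_distance_series(traj)
    r_on = r_on_nm * NM_TO_ANGSTROM
    r_off = r_off_nm * NM_TO_ANGSTROM
    F = traj.n_frames

    events: list[ContactEvent] = []
    within_on = d <= r_on
    within_off = d <= r_off
    for li, lid in enumerate(lipids):
        for ri, rid in enumerate(residues):
            on = within_on[:, li, ri]
            off = within_off[:, li, ri]
            active = False
            start = 0
            for f in range(F):
                if not active:
                    if on[f]:
                        active = True
                        start = f
                elif not off[f]:
                    events.append(ContactEvent(lid, rid, start, f - 1))
                    active = False
            if active:
                events.append(ContactEvent(lid, rid, start, F - 1))
    return events


def events_to_frame_mask(
    events: Iterable[ContactEvent], n_frames: int
) -> dict[tuple[int, ResidueId], np.ndarray]:
    """Boolean in-contact mask per (lipid, residue) pair."""
    masks: dict[tuple[int, ResidueId], np.ndarray] = {}
    for ev in events:
        if ev.end_frame >= n_frames:
            raise ValueError(f"event {ev} exceeds n_frames={n_frames}")
        key = (ev.lipid_id, ev.residue)
        if key not in masks:
            masks[key] = np.zeros(n_frames, dtype=bool)
        masks[key][ev.start_frame : ev.end_frame + 1] = True
    return masks


def residue_occupancy(events: Iterable[ContactEvent], n_frames: int) -> pd.DataFrame:
    """Percentage of frames each residue is contacted by at least one lipid.

    Overlapping events from different lipids count once per frame (union
    semantics).  Residues with no events are absent from the table.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    union: dict[ResidueId, np.ndarray] = {}
    for (lid, rid), mask in events_to_frame_mask(events, n_frames).items():
        if rid not in union:
            union[rid] = mask.copy()
        else:
            union[rid] |= mask
    rows = [
        {
            "chain_id": rid[0],
            "residue_number": rid[1],
            "occupancy_pct": 100.0 * mask.sum() / n_frames,
        }
        for rid, mask in union.items()
    ]
    table = pd.DataFrame(rows, columns=["chain_id", "residue_number", "occupancy_pct"])
    if len(table):
        table = table.sort_values(
            ["occupancy_pct", "chain_id", "residue_number"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return table


def residence_times(
    events: Iterable[ContactEvent], frame_stride_ps: float = 1000.0
) -> pd.DataFrame:
    """Mean and maximum contact duration per residue, in ps."""
    per_res: dict[ResidueId, list[int]] = {}
    for ev in events:
        per_res.setdefault(ev.residue, []).append(ev.duration_frames)
    rows = [
        {
            "chain_id": rid[0],
            "residue_number": rid[1],
            "n_events": len(durs),
            "mean_duration_ps": float(np.mean(durs)) * frame_stride_ps,
            "max_duration_ps": float(np.max(durs)) * frame_stride_ps,
        }
        for rid, durs in per_res.items()
    ]
    table = pd.DataFrame(
        rows,
        columns=["chain_id", "residue_number", "n_events", "mean_duration_ps", "max_duration_ps"],
    )
    if len(table):
        table = table.sort_values(
            ["mean_duration_ps", "chain_id", "residue_number"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return table


def site_occupancy(
    residues: Iterable[ResidueId], events: Iterable[ContactEvent], n_frames: int
) -> float:
    """Percentage of frames in which >=1 lipid contacts >=1 site residue."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    residues = set(residues)
    if not residues:
        raise ValueError("site has no residues")
    mask = np.zeros(n_frames, dtype=bool)
    for (lid, rid), m in events_to_frame_mask(events, n_frames).items():
        if rid in residues:
            mask |= m
    return 100.0 * float(mask.sum()) / n_frames


def cluster_binding_sites(
    events: Sequence[ContactEvent],
    n_frames: int,
    min_edge_pct: float = 5.0,
) -> tuple[list[BindingSite], list[ResidueId]]:
    """Cluster contacted residues into binding sites by lipid commonality.

    Two residues are connected when some single lipid molecule is in
    contact with both simultaneously in at least ``min_edge_pct`` percent
    of frames; connected components with >=2 residues become
    :class:`BindingSite` objects (ordered by descending occupancy), and
    contacted residues left on their own are returned separately.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    events = list(events)
    if not events:
        return [], []
    masks = events_to_frame_mask(events, n_frames)
    by_lipid: dict[int, dict[ResidueId, np.ndarray]] = {}
    for (lid, rid), m in masks.items():
        by_lipid.setdefault(lid, {})[rid] = m

    all_residues = sorted({ev.residue for ev in events})
    min_frames = min_edge_pct / 100.0 * n_frames
    g = nx.Graph()
    g.add_nodes_from(all_residues)
    # co-contact frames: a frame counts for (i, j) when at least one lipid
    # touches both residues in that frame
    co: dict[tuple[ResidueId, ResidueId], np.ndarray] = {}
    for lid, res_masks in by_lipid.items():
        rids = sorted(res_masks)
        for a in range(len(rids)):
            for b in range(a + 1, len(rids)):
                key = (rids[a], rids[b])
                both = res_masks[rids[a]] & res_masks[rids[b]]
                if key in co:
                    co[key] |= both
                else:
                    co[key] = both
    for (ri, rj), both in co.items():
        if both.sum() >= min_frames and both.any():
            g.add_edge(ri, rj)

    sites: list[BindingSite] = []
    singletons: list[ResidueId] = []
    components = [sorted(c) for c in nx.connected_components(g)]
    occ_all = residue_occupancy(events, n_frames)
    occ_lookup = {
        (row.chain_id, row.residue_number): row.occupancy_pct
        for row in occ_all.itertuples()
    }
    scored = []
    for comp in components:
        if len(comp) < 2:
            singletons.extend(comp)
            continue
        occ = site_occupancy(comp, events, n_frames)
        scored.append((occ, comp))
    scored.sort(key=lambda t: (-t[0], t[1][0]))
    for sid, (occ, comp) in enumerate(scored, start=1):
        top = pd.DataFrame(
            [
                {
                    "chain_id": rid[0],
                    "residue_number": rid[1],
                    "occupancy_pct": occ_lookup.get(rid, 0.0),
                }
                for rid in comp
            ]
        ).sort_values(
            ["occupancy_pct", "chain_id", "residue_number"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
        sites.append(
            BindingSite(
                site_id=sid,
                residues=frozenset(comp),
                occupancy_pct=occ,
                top_residue_occupancies=top,
            )
        )
    singletons.sort()
    return sites, singletons


# ----------------------------------------------------------------------
# membrane-plane density


@dataclass
class DensityMap:
    """Mean lipid bead count per grid cell per frame, in the membrane plane."""

    counts: np.ndarray  # (nx, ny), mean beads per frame
    x_edges: np.ndarray
    y_edges: np.ndarray
    spacing: float
    n_frames: int
    leaflet: str

    @property
    def origin(self) -> tuple[float, float]:
        return float(self.x_edges[0]), float(self.y_edges[0])

    def total_mass(self) -> float:
        """Summed mean counts; times n_frames this is the total number of
        binned bead observations."""
        return float(self.counts.sum())

    def save_text(self, matrix_path: str | Path, header_path: str | Path) -> None:
        np.savetxt(matrix_path, self.counts, fmt="%.8g")
        header = {
            "origin": [float(self.x_edges[0]), float(self.y_edges[0])],
            "spacing": self.spacing,
            "shape": list(self.counts.shape),
            "n_frames": self.n_frames,
            "leaflet": self.leaflet,
            "units": "mean beads per frame per cell; x/y in angstrom",
        }
        Path(header_path).write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")


def density_map(
    traj: FrameSeries,
    grid_spacing: float = 2.0,
    leaflet: str = "both",
    midplane_z: float = 0.0,
    bead_names: Sequence[str] | None = None,
) -> DensityMap:
    """2D membrane-plane histogram of lipid bead positions, averaged over
    frames.

    ``leaflet`` selects beads by z relative to ``midplane_z``: "inner"
    (z <= midplane, the intracellular leaflet), "outer" (z > midplane) or
    "both".  The grid covers the xy bounding box of the selected beads
    over the whole trajectory, so the total mass equals the mean number of
    selected beads per frame.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if leaflet not in ("inner", "outer", "both"):
        raise ValueError(f"unknown leaflet {leaflet!r}")
    coords = traj.bead_coords  # (F, B, 3)
    if bead_names is not None:
        sel = np.array([n in set(bead_names) for n in traj.bead_names], dtype=bool)
        if not sel.any():
            raise ValueError("no beads match the requested names")
        coords = coords[:, sel, :]
    flat = coords.reshape(-1, 3)
    if leaflet == "inner":
        flat = flat[flat[:, 2] <= midplane_z]
    elif leaflet == "outer":
        flat = flat[flat[:, 2] > midplane_z]
    if len(flat) == 0:
        raise ValueError("no bead observations in the selected leaflet")

    x_min, y_min = flat[:, 0].min(), flat[:, 1].min()
    x_max, y_max = flat[:, 0].max(), flat[:, 1].max()
    nx_ = max(1, int(np.ceil((x_max - x_min) / grid_spacing)))
    ny_ = max(1, int(np.ceil((y_max - y_min) / grid_spacing)))
    x_edges = x_min + grid_spacing * np.arange(nx_ + 1)
    y_edges = y_min + grid_spacing * np.arange(ny_ + 1)
    # widen the last edge minutely so max-coordinate beads stay binned
    x_edges[-1] = max(x_edges[-1], x_max + 1e-9)
    y_edges[-1] = max(y_edges[-1], y_max + 1e-9)
    h, _, _ = np.histogram2d(flat[:, 0], flat[:, 1], bins=[x_edges, y_edges])
    return DensityMap(
        counts=h / traj.n_frames,
        x_edges=x_edges,
        y_edges=y_edges,
        spacing=grid_spacing,
        n_frames=traj.n_frames,
        leaflet=leaflet,
    )
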