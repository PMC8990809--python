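"""Deterministic synthetic fixtures: toy C_n oligomers, planted pose sets
and scripted lipid dwell trajectories.

These generators exist so the whole analysis stack can be exercised and
validated without any external structures or simulations: every generator
also records the *planted truth* (cluster labels, intended orientations,
dwell schedules) against which recovered quantities can be checked.  The
geometry is idealized - regular inositol hexagons, helical pegs for side
chains, teleporting lipids - because only centroids and distances matter
to the analyses under test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .poses import PHOSPHO_POSITIONS, LigandPose, SPECIES
from .structures import (
    FrameSeries,
    ProteinModel,
    ResidueId,
    SymmetrySpec,
    rotate_about_z,
)

__all__ = [
    "PoseSetTruth",
    "DwellTruth",
    "SiteDef",
    "make_toy_oligomer",
    "make_pose_set",
    "make_dwell_trajectory",
]


# ----------------------------------------------------------------------
# toy oligomer

# side-chain peg templates: (atom_name, element, radial_offset, z_offset)
_SIDECHAINS: dict[str, list[tuple[str, str, float, float]]] = {
    "LYS": [("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.2), ("CD", "C", 4.1, 0.0),
            ("CE", "C", 5.3, 0.2), ("NZ", "N", 6.5, 0.0)],
    "ARG": [("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.2), ("CD", "C", 4.1, 0.0),
            ("NE", "N", 5.3, 0.2), ("CZ", "C", 6.3, 0.0)],
    "SER": [("CB", "C", 1.5, 0.0), ("OG", "O", 2.6, 0.3)],
    "LEU": [("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.2), ("CD1", "C", 3.9, 0.8),
            ("CD2", "C", 3.9, -0.8)],
    "THR": [("CB", "C", 1.5, 0.0), ("OG1", "O", 2.5, 0.6), ("CG2", "C", 2.7, -0.7)],
    "ASN": [("CB", "C", 1.5, 0.0), ("CG", "C", 2.8, 0.2), ("OD1", "O", 3.8, 0.7),
            ("ND2", "N", 3.8, -0.6)],
}
_RESIDUE_CYCLE = ("LYS", "ARG", "SER", "LEU", "THR", "ASN")
_BACKBONE = [("N", "N", -0.6, 0.4), ("CA", "C", 0.0, 0.0),
             ("C", "C", -0.4, -0.5), ("O", "O", -1.3, -0.6)]


def make_toy_oligomer(
    n_chains: int = 4,
    residues_per_chain: int = 12,
    radius: float = 18.0,
    seed: int = 0,
    z_span: tuple[float, float] = (-25.0, 25.0),
) -> ProteinModel:
    """An exactly C_n-symmetric toy oligomer of idealized helical subunits.

    One subunit is built with residues spaced along z in ``z_span`` on a
    cylinder of the given radius, side chains pointing radially outward
    (hence solvent exposed); the other chains are exact images under
    k * 360/n rotations, so the model's symmetry is perfect by
    construction.  A small seeded radial jitter is applied to the template
    subunit before replication, keeping the symmetry exact while varying
    the geometry between seeds.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if residues_per_chain < 1 or radius <= 0:
        raise ValueError("nonpositive dimensions")
    rng = np.random.default_rng(seed)
    z_lo, z_hi = z_span
    chains = [chr(ord("A") + i) for i in range(n_chains)]

    names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    chain_ids: list[str] = []
    resnums: list[int] = []
    resnames: list[str] = []

    # template subunit (chain A), azimuth within (-30 deg, +30 deg)
    template: list[tuple[str, str, np.ndarray, int, str]] = []
    R = residues_per_chain
    for i in range(R):
        z = z_lo + (z_hi - z_lo) * (i / max(R - 1, 1))
        az = math.radians(-15.0 + 30.0 * (i / max(R - 1, 1)))
        r0 = radius + rng.uniform(-0.3, 0.3)
        resname = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        u = np.array([math.cos(az), math.sin(az), 0.0])
        for atom_name, elem, dr, dz in _BACKBONE + _SIDECHAINS[resname]:
            pos = (r0 + dr) * u + np.array([0.0, 0.0, z + dz])
            template.append((atom_name, elem, pos, i + 1, resname))

    for k, chain in enumerate(chains):
        for atom_name, elem, pos, resnum, resname in template:
            names.append(atom_name)
            elements.append(elem)
            coords.append(rotate_about_z(pos, k, n_chains))
            chain_ids.append(chain)
            resnums.append(resnum)
            resnames.append(resname)

    return ProteinModel(
        atom_names=names,
        elements=elements,
        coords=np.array(coords),
        chain_ids=chain_ids,
        residue_numbers=resnums,
        residue_names=resnames,
        symmetry=SymmetrySpec.cyclic(chains),
    )


def max_radius(model: ProteinModel) -> float:
    return float(np.max(np.linalg.norm(model.coords[:, :2], axis=1)))


# ----------------------------------------------------------------------
# planted pose sets


@dataclass
class PoseSetTruth:
    """Ground truth planted by :func:`make_pose_set`."""

    centers: np.ndarray                     # (k, 3) planted cluster centers
    cluster_labels: np.ndarray              # per-pose center index
    misoriented: np.ndarray                 # per-pose bool (tail flipped away)
    contact_probs: dict[ResidueId, float] = field(default_factory=dict)
    species: str = "PI45P2"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "cluster_labels": self.cluster_labels.tolist(),
            "misoriented": self.misoriented.astype(int).tolist(),
            "contact_probs": {f"{c}:{r}": p for (c, r), p in self.contact_probs.items()},
            "species": self.species,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _headgroup_template(species: str) -> tuple[list[str], list[str], np.ndarray]:
    """Idealized headgroup in a local frame: inositol hexagon in the xy
    plane centered on the origin, glycerol C1 above the ring (+z = toward
    the membrane when correctly oriented)."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    names: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    ring_r = 1.4
    for j in range(6):  # C1..C6 at 60 deg steps, position p at angle (p-1)*60
        a = math.radians(60.0 * j)
        names.append(f"C{j + 1}")
        elements.append("C")
        coords.append([ring_r * math.cos(a), ring_r * math.sin(a), 0.0])
    phospho = set(PHOSPHO_POSITIONS[species])
    for p in range(2, 7):
        a = math.radians(60.0 * (p - 1))
        u = (math.cos(a), math.sin(a))
        if p in phospho:
            names += [f"P{p}", f"O{p}A", f"O{p}B", f"O{p}C"]
            elements += ["P", "O", "O", "O"]
            coords += [
                [2.9 * u[0], 2.9 * u[1], 0.0],
                [3.9 * u[0], 3.9 * u[1], 0.8],
                [3.9 * u[0], 3.9 * u[1], -0.8],
                [4.3 * u[0], 4.3 * u[1], 0.0],
            ]
        else:
            names.append(f"O{p}")
            elements.append("O")
            coords.append([2.5 * u[0], 2.5 * u[1], 0.0])
    # P1 phosphate bridging to the glycerol C1 carbon, both above the ring
    names += ["P1", "C1G"]
    elements += ["P", "C"]
    coords += [[ring_r, 0.0, 1.3], [ring_r, 0.0, 2.6]]
    return names, elements, np.array(coords)


def make_pose_set(
    model: ProteinModel,
    centers: Sequence[Sequence[float]],
    n_per_center: int = 100,
    scatter_sigma: float = 2.0,
    frac_misoriented: float = 0.0,
    seed: int = 0,
    species: str = "PI45P2",
    contact_probs: dict[ResidueId, float] | None = None,
) -> tuple[list[LigandPose], PoseSetTruth]:
    """Planted pose clusters around the given centers.

    Each pose is the idealized headgroup template, randomly spun about its
    own z axis, translated to its center plus isotropic Gaussian scatter
    of ``scatter_sigma``.  Exactly ``round(frac_misoriented * n)`` poses
    (chosen at random) have their tail flipped to face away from the
    membrane, so the planted acceptance fraction is 1 - frac_misoriented
    up to rounding.

    ``contact_probs`` optionally plants per-residue contact probabilities:
    for each listed residue every pose carries a probe oxygen that sits
    within 4 A of that residue with the given probability and far outside
    the protein otherwise (the atom list stays constant across poses).
    """
    if scatter_sigma < 0:
        raise ValueError("scatter_sigma must be >= 0")
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if len(centers) == 0:
        raise ValueError("at least one center required")
    rng = np.random.default_rng(seed)
    names, elements, local = _headgroup_template(species)
    contact_probs = dict(contact_probs or {})

    probe_targets: list[tuple[str, np.ndarray, float]] = []
    if contact_probs:
        by_res = model.atom_indices_by_residue()
        for j, (rid, prob) in enumerate(sorted(contact_probs.items())):
            idx = by_res.get(rid)
            if idx is None:
                raise KeyError(f"contact_probs residue {rid} not in model")
            # outermost heavy atom of the residue, probe sits 2 A outside it
            heavy = idx[model.heavy_mask[idx]]
            radial = np.linalg.norm(model.coords[heavy][:, :2], axis=1)
            tip = model.coords[heavy[int(np.argmax(radial))]]
            u = tip[:2] / max(np.linalg.norm(tip[:2]), 1e-9)
            near = tip + np.array([2.0 * u[0], 2.0 * u[1], 0.0])
            probe_targets.append((f"OX{j + 1}", near, prob))

    n_total = len(centers) * n_per_center
    flip = np.zeros(n_total, dtype=bool)
    n_flip = int(round(frac_misoriented * n_total))
    flip[rng.permutation(n_total)[:n_flip]] = True

    far_radius = max_radius(model) + 60.0
    poses: list[LigandPose] = []
    labels = np.repeat(np.arange(len(centers)), n_per_center)
    for i in range(n_total):
        center = centers[labels[i]] + rng.normal(0.0, scatter_sigma, size=3)
        spin = rng.uniform(0.0, 2.0 * math.pi)
        c, s = math.cos(spin), math.sin(spin)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        xyz = local @ rot.T
        if flip[i]:
            xyz = xyz * np.array([1.0, 1.0, -1.0])
        xyz = xyz + center

        pose_names = list(names)
        pose_elements = list(elements)
        rows = [xyz]
        for pname, near, prob in probe_targets:
            pose_names.append(pname)
            pose_elements.append("O")
            if rng.random() < prob:
                rows.append(near[None, :])
            else:
                a = rng.uniform(0.0, 2.0 * math.pi)
                rows.append(np.array([[far_radius * math.cos(a),
                                       far_radius * math.sin(a), -40.0]]))
        poses.append(
            LigandPose(
                pose_id=i + 1,
                species=species,
                atom_names=pose_names,
                elements=pose_elements,
                coords=np.vstack(rows),
            )
        )

    truth = PoseSetTruth(
        centers=centers,
        cluster_labels=labels,
        misoriented=flip,
        contact_probs=contact_probs,
        species=species,
        seed=seed,
    )
    return poses, truth


# ----------------------------------------------------------------------
# scripted dwell trajectories


@dataclass(frozen=True)
class SiteDef:
    """A planted binding site: which residues, how the lipid dwells.

    Exactly one of ``occupancy_pct`` (a single contiguous dwell occupying
    that share of the trajectory) or ``dwell_mean_frames`` (alternating
    geometric dwell / off blocks) should be set; a site with
    ``occupancy_pct=0`` is planted but never visited.
    """

    residues: tuple[ResidueId, ...]
    occupancy_pct: float | None = None
    dwell_mean_frames: float | None = None
    gap_mean_frames: float | None = None
    n_lipids: int = 1


@dataclass
class DwellTruth:
    """Planted dwell schedule and the occupancies it implies."""

    schedules: list[tuple[int, int, int, int]]  # (lipid_id, site_idx, start, end)
    residue_occupancy: dict[ResidueId, float]
    site_residues: list[tuple[ResidueId, ...]]
    n_frames: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schedules": [list(s) for s in self.schedules],
            "residue_occupancy": {
                f"{c}:{r}": v for (c, r), v in sorted(self.residue_occupancy.items())
            },
            "site_residues": [[f"{c}:{r}" for c, r in site] for site in self.site_residues],
            "n_frames": self.n_frames,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _site_anchor_points(model: ProteinModel, residues: Sequence[ResidueId]) -> np.ndarray:
    """One bead anchor per site residue: 3.5 A radially outside the
    residue's outermost heavy atom (inside the 0.5 nm inner cutoff)."""
    by_res = model.atom_indices_by_residue()
    anchors = []
    for rid in residues:
        idx = by_res.get(rid)
        if idx is None:
            raise KeyError(f"site residue {rid} not in model")
        heavy = idx[model.heavy_mask[idx]]
        radial = np.linalg.norm(model.coords[heavy][:, :2], axis=1)
        tip = model.coords[heavy[int(np.argmax(radial))]]
        u = tip[:2] / max(np.linalg.norm(tip[:2]), 1e-9)
        anchors.append(tip + np.array([3.5 * u[0], 3.5 * u[1], 0.0]))
    return np.array(anchors)


def _check_anchor_clearance(
    model: ProteinModel,
    site: SiteDef,
    anchors: np.ndarray,
    clearance: float,
) -> None:
    """Planted placements must not graze residues outside the site, or the
    schedule would not be the truth it claims to be."""
    site_set = set(site.residues)
    by_res = model.atom_indices_by_residue()
    for rid, idx in by_res.items():
        if rid in site_set:
            continue
        heavy = idx[model.heavy_mask[idx]]
        d = np.linalg.norm(
            model.coords[heavy][None, :, :] - anchors[:, None, :], axis=-1
        )
        if d.min() <= clearance:
            raise ValueError(
                f"impossible schedule: dwell placement for site {site.residues} "
                f"comes within {d.min():.2f} A of non-site residue {rid}; "
                "choose more exposed or more separated site residues"
            )


def make_dwell_trajectory(
    model: ProteinModel,
    sites: Sequence[SiteDef],
    n_frames: int,
    seed: int = 0,
    frame_stride_ps: float = 1000.0,
    anchor_clearance: float = 5.5,
) -> tuple[FrameSeries, DwellTruth]:
    """Scripted lipid dwell trajectory over a rigid protein.

    Each site's lipids alternate between far-field "free diffusion"
    (parked well outside both contact cutoffs) and dwells during which one
    headgroup bead sits 3.5 A outside each planted site residue, i.e.
    inside the 0.5 nm inner cutoff.  Dwell and gap lengths are geometric
    with the requested means; consecutive dwells are separated by at least
    one off frame so detected events are in one-to-one correspondence with
    scheduled dwells.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not sites:
        raise ValueError("at least one SiteDef required")
    rng = np.random.default_rng(seed)
    far_r = max_radius(model) + 50.0

    lipid_ids: list[int] = []
    bead_names: list[str] = []
    bead_anchor: list[np.ndarray] = []   # per bead, dwell-time position
    bead_far: list[np.ndarray] = []      # per bead, off-time position
    dwell_mask: list[np.ndarray] = []    # per lipid, frames in dwell
    schedules: list[tuple[int, int, int, int]] = []

    lipid_counter = 0
    for s_idx, site in enumerate(sites):
        anchors = _site_anchor_points(model, site.residues)
        _check_anchor_clearance(model, site, anchors, anchor_clearance)
        for _ in range(site.n_lipids):
            lipid_counter += 1
            lid = lipid_counter
            mask = np.zeros(n_frames, dtype=bool)
            if site.occupancy_pct is not None:
                k = int(round(site.occupancy_pct / 100.0 * n_frames))
                k = min(k, n_frames)
                if k > 0:
                    mask[:k] = True
                    schedules.append((lid, s_idx, 0, k - 1))
            elif site.dwell_mean_frames is not None:
                gap_mean = site.gap_mean_frames or site.dwell_mean_frames
                t = int(rng.geometric(min(1.0, 1.0 / gap_mean)))
                while t < n_frames:
                    dwell = int(rng.geometric(min(1.0, 1.0 / site.dwell_mean_frames)))
                    end = min(t + dwell - 1, n_frames - 1)
                    mask[t : end + 1] = True
                    schedules.append((lid, s_idx, t, end))
                    t = end + 1 + int(rng.geometric(min(1.0, 1.0 / gap_mean)))
            # else: a planted site that is never visited

            far_az = 2.0 * math.pi * (lid / (sum(s.n_lipids for s in sites) + 1.0))
            far_base = np.array([far_r * math.cos(far_az), far_r * math.sin(far_az), -45.0])
            for b, anchor in enumerate(anchors):
                lipid_ids.append(lid)
                bead_names.append("PO4" if b == 0 else f"HG{b}")
                bead_anchor.append(anchor)
                bead_far.append(far_base + np.array([0.0, 0.0, 2.0 * b]))
            dwell_mask.append(mask)

    bead_anchor_arr = np.array(bead_anchor)
    bead_far_arr = np.array(bead_far)
    lipid_ids_arr = np.array(lipid_ids, dtype=int)
    bead_coords = np.empty((n_frames, len(lipid_ids), 3))
    unique_lids = list(dict.fromkeys(lipid_ids))
    for li, lid in enumerate(unique_lids):
        sel = lipid_ids_arr == lid
        mask = dwell_mask[li]
        bead_coords[:, sel, :] = np.where(
            mask[:, None, None], bead_anchor_arr[sel][None], bead_far_arr[sel][None]
        )

    protein_coords = np.broadcast_to(
        model.coords[None, :, :], (n_frames, model.n_atoms, 3)
    ).copy()

    traj = FrameSeries(
        protein_chain_ids=model.chain_ids,
        protein_residue_numbers=model.residue_numbers,
        protein_residue_names=model.residue_names,
        protein_atom_names=model.atom_names,
        protein_coords=protein_coords,
        lipid_ids=lipid_ids_arr,
        bead_names=bead_names,
        bead_coords=bead_coords,
        frame_stride_ps=frame_stride_ps,
    )

    # truth occupancy per planted residue: union of its site's lipid dwells
    truth_occ: dict[ResidueId, float] = {}
    for s_idx, site in enumerate(sites):
        union = np.zeros(n_frames, dtype=bool)
        for li, lid in enumerate(unique_lids):
            for (l2, s2, a, b) in schedules:
                if l2 == lid and s2 == s_idx:
                    union[a : b + 1] = True
        for rid in site.residues:
            prev = truth_occ.get(rid, 0.0)
            truth_occ[rid] = max(prev, 100.0 * union.sum() / n_frames)
    truth = DwellTruth(
        schedules=schedules,
        residue_occupancy=truth_occ,
        site_residues=[tuple(site.residues) for site in sites],
        n_frames=n_frames,
    )
    return traj, truth
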