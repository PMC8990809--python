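"""Docked phosphoinositide-headgroup pose analysis.

A docked headgroup (truncated at the glycerol C1 carbon) is reduced to a
three-centroid *pose vector*: the glycerol C1 carbon, the inositol ring,
and an anchor phosphate at the 3/4/5 position.  Poses are accepted when the
tail direction (inositol centroid -> C1 centroid) is parallel to the
membrane plane or points toward the bilayer; accepted poses are rotated
into a reference symmetry wedge before clustering, and their contacting
residues are identified with a heavy-atom distance cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import (
    MembraneFrame,
    ProteinModel,
    ResidueId,
    SymmetrySpec,
    rotate_about_z,
)

__all__ = [
    "SPECIES",
    "PHOSPHO_POSITIONS",
    "AtomGroupMap",
    "DEFAULT_ATOM_GROUPS",
    "default_atom_groups",
    "LigandPose",
    "PoseVector",
    "compute_pose_vector",
    "orientation_filter",
    "reduce_to_reference_wedge",
    "contact_residues",
    "residue_contact_frequencies",
]

SPECIES = ("PI", "PI3P", "PI4P", "PI5P", "PI34P2", "PI35P2", "PI45P2", "PI345P3")

#: phosphorylated inositol positions per species
PHOSPHO_POSITIONS: dict[str, tuple[int, ...]] = {
    "PI": (),
    "PI3P": (3,),
    "PI4P": (4,),
    "PI5P": (5,),
    "PI34P2": (3, 4),
    "PI35P2": (3, 5),
    "PI45P2": (4, 5),
    "PI345P3": (3, 4, 5),
}


@dataclass(frozen=True)
class AtomGroupMap:
    """Atom names defining the three centroid groups of one species.

    ``anchor_phosphate_atoms`` names a phosphate at the 3, 4 or 5 position;
    for unphosphorylated PI the fallback is the C4 hydroxyl oxygen.
    """

    glycerol_c1_atoms: tuple[str, ...]
    inositol_ring_atoms: tuple[str, ...]
    anchor_phosphate_atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = (
            self.glycerol_c1_atoms,
            self.inositol_ring_atoms,
            self.anchor_phosphate_atoms,
        )
        if any(len(g) == 0 for g in groups):
            raise ValueError("all three centroid groups must be nonempty")
        names = [n for g in groups for n in g]
        if len(set(names)) != len(names):
            raise ValueError("centroid groups must be disjoint")


def _anchor_position(species: str) -> int | None:
    """Anchor phosphate position: the lowest phosphorylated 3/4/5 position."""
    pos = PHOSPHO_POSITIONS[species]
    return min(pos) if pos else None


def default_atom_groups(species: str) -> AtomGroupMap:
    """Default atom-name map for the idealized headgroup naming scheme.

    Inositol ring carbons are C1..C6; a phosphate at position *n* is
    ``Pn`` with terminal oxygens ``OnA/OnB/OnC``; free hydroxyl oxygens are
    ``On``; the glycerol C1 carbon is ``C1G``.  Real docking output with
    different names is handled by supplying a custom :class:`AtomGroupMap`
    (e.g. from the YAML config).
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    n = _anchor_position(species)
    if n is None:  # PI: fall back to the C4 hydroxyl oxygen
        anchor: tuple[str, ...] = ("O4",)
    else:
        anchor = (f"P{n}", f"O{n}A", f"O{n}B", f"O{n}C")
    return AtomGroupMap(
        glycerol_c1_atoms=("C1G",),
        inositol_ring_atoms=("C1", "C2", "C3", "C4", "C5", "C6"),
        anchor_phosphate_atoms=anchor,
    )


DEFAULT_ATOM_GROUPS: dict[str, AtomGroupMap] = {s: default_atom_groups(s) for s in SPECIES}


@dataclass
class LigandPose:
    """One docked headgroup pose (atoms truncated at the glycerol C1)."""

    pose_id: int
    species: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    docking_energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atom_names) != len(self.coords) or len(self.elements) != len(self.coords):
            raise ValueError("atom attribute arrays must have equal length")
        if len(self.atom_names) == 0:
            raise ValueError("pose has no atoms")

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def atom_coords(self, names: Sequence[str], group: str) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.atom_names)}
        rows = []
        for n in names:
            if n not in index:
                raise KeyError(
                    f"pose {self.pose_id}: atom {n!r} of group {group!r} not found"
                )
            rows.append(index[n])
        return self.coords[rows]


@dataclass(frozen=True)
class PoseVector:
    """Three-centroid reduction of a pose, plus the wedge rotation applied."""

    pose_id: int
    c1_centroid: np.ndarray
    inositol_centroid: np.ndarray
    phosphate_centroid: np.ndarray
    wedge_rotation_k: int = 0

    def __post_init__(self) -> None:
        for name in ("c1_centroid", "inositol_centroid", "phosphate_centroid"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        if np.linalg.norm(self.c1_centroid - self.inositol_centroid) == 0.0:
            raise ValueError("degenerate pose: zero-length tail vector")

    @property
    def tail_vector(self) -> np.ndarray:
        """Inositol centroid -> glycerol C1 (the lipid-tail attachment direction)."""
        return self.c1_centroid - self.inositol_centroid

    def centroids(self) -> np.ndarray:
        return np.stack([self.c1_centroid, self.inositol_centroid, self.phosphate_centroid])


def compute_pose_vector(pose: LigandPose, groups: AtomGroupMap | None = None) -> PoseVector:
    """Reduce a pose to its three group centroids (unweighted means)."""
    if groups is None:
        groups = DEFAULT_ATOM_GROUPS[pose.species]
    c1 = pose.atom_coords(groups.glycerol_c1_atoms, "glycerol_c1").mean(axis=0)
    ino = pose.atom_coords(groups.inositol_ring_atoms, "inositol_ring").mean(axis=0)
    pho = pose.atom_coords(groups.anchor_phosphate_atoms, "anchor_phosphate").mean(axis=0)
    return PoseVector(
        pose_id=pose.pose_id,
        c1_centroid=c1,
        inositol_centroid=ino,
        phosphate_centroid=pho,
        wedge_rotation_k=0,
    )


def orientation_filter(
    vec: PoseVector,
    frame: MembraneFrame | None = None,
    tolerance_deg: float = 15.0,
) -> tuple[bool, float]:
    """Membrane-orientation acceptance test.

    The elevation of the tail vector above the membrane plane is
    ``phi = asin(t_z / |t|)`` with +z pointing from the intracellular side
    toward the bilayer midplane.  A pose is accepted when the glycerol C1
    lies parallel to the membrane or faces it: ``phi >= -tolerance_deg``.
    Returns ``(accepted, phi_degrees)``.
    """
    t = vec.tail_vector
    norm = float(np.linalg.norm(t))
    if norm == 0.0:
        raise ValueError("zero-length tail vector")
    phi = math.degrees(math.asin(float(t[2]) / norm))
    return phi >= -tolerance_deg, phi


def reduce_to_reference_wedge(vec: PoseVector, sym: SymmetrySpec) -> PoseVector:
    """Rotate a pose vector into the reference symmetry wedge.

    Finds the unique k in [0, order) for which the azimuth of the rotated
    inositol centroid lies in [0, 360/order) degrees, and applies that
    rotation to all three centroids.
    """
    x, y = float(vec.inositol_centroid[0]), float(vec.inositol_centroid[1])
    if x == 0.0 and y == 0.0:
        raise ValueError("inositol centroid on the symmetry axis: azimuth undefined")
    wedge = 2.0 * math.pi / sym.order
    az = math.atan2(y, x) % (2.0 * math.pi)
    k = (-int(az // wedge)) % sym.order
    return PoseVector(
        pose_id=vec.pose_id,
        c1_centroid=rotate_about_z(vec.c1_centroid, k, sym.order),
        inositol_centroid=rotate_about_z(vec.inositol_centroid, k, sym.order),
        phosphate_centroid=rotate_about_z(vec.phosphate_centroid, k, sym.order),
        wedge_rotation_k=(vec.wedge_rotation_k + k) % sym.order,
    )


def contact_residues(
    pose: LigandPose,
    model: ProteinModel,
    cutoff: float = 4.0,
    rotation_k: int = 0,
    sym_order: int | None = None,
) -> set[ResidueId]:
    """Residues with >=1 heavy atom within ``cutoff`` (inclusive, angstrom)
    of >=1 ligand heavy atom, after rotating the pose by ``rotation_k``
    symmetry steps about z.  Hydrogens are excluded on both sides.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    order = sym_order if sym_order is not None else model.symmetry.order
    lig = pose.coords[pose.heavy_mask]
    if len(lig) == 0:
        raise ValueError("pose has no heavy atoms")
    if rotation_k % order:
        lig = rotate_about_z(lig, rotation_k, order)
    heavy = model.heavy_mask
    prot = model.coords[heavy]
    if len(prot) == 0:
        raise ValueError("model has no heavy atoms")
    d = cdist(prot, lig)
    hit = (d <= cutoff).any(axis=1)
    chains = model.chain_ids[heavy][hit]
    resnums = model.residue_numbers[heavy][hit]
    return {(c, int(r)) for c, r in zip(chains, resnums)}


def residue_contact_frequencies(
    accepted: Iterable[tuple[LigandPose, PoseVector]],
    model: ProteinModel,
    cutoff: float = 4.0,
    contact_sets: Sequence[set[ResidueId]] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-residue contact frequency across accepted, wedge-reduced poses.

    For every residue contacted at least once, reports the percentage of
    accepted poses whose 4 A contact set contains it.  Returns the table
    (sorted by descending frequency, then chain/residue) and the total
    number of distinct residues contacted by any accepted pose.

    ``contact_sets`` may supply precomputed contact sets (in the same order
    as ``accepted``) to avoid recomputation in pipelines.
    """
    pairs = list(accepted)
    if not pairs:
        raise ValueError("no accepted poses")
    if contact_sets is None:
        contact_sets = [
            contact_residues(pose, model, cutoff=cutoff, rotation_k=vec.wedge_rotation_k)
            for pose, vec in pairs
        ]
    counts: dict[ResidueId, int] = {}
    for cs in contact_sets:
        for rid in cs:
            counts[rid] = counts.get(rid, 0) + 1
    n = len(pairs)
    rows = [
        {
            "chain_id": rid[0],
            "residue_number": rid[1],
            "residue_name": model.residue_name_of(rid),
            "n_poses": c,
            "frequency_pct": 100.0 * c / n,
        }
        for rid, c in counts.items()
    ]
    table = pd.DataFrame(
        rows,
        columns=["chain_id", "residue_number", "residue_name", "n_poses", "frequency_pct"],
    )
    if len(table):
        table = table.sort_values(
            ["frequency_pct", "chain_id", "residue_number"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return table, len(counts)
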