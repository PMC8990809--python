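"""Core structural types: protein models, membrane frame, rotational symmetry.

Coordinates are Cartesian angstroms throughout the package, with the membrane
normal along +z (the convention of membrane-frame-oriented structures such as
OPM output).  The intracellular side sits below the bilayer midplane, so "+z"
always points from the cytoplasm toward the membrane core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MembraneFrame",
    "SymmetrySpec",
    "ProteinModel",
    "FrameSeries",
    "ResidueId",
    "rotate_about_z",
    "rotation_matrix_z",
    "accessible_leaflet_residues",
    "BACKBONE_ATOM_NAMES",
]

#: residue identity used everywhere: (chain_id, residue_number)
ResidueId = tuple[str, int]

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element, position (angstrom) and residue identity."""

    atom_name: str
    element: str
    coord: tuple[float, float, float]
    chain_id: str
    residue_number: int
    residue_name: str

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.atom_name}")


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane geometry in the protein frame.

    The membrane normal is fixed as +z.  ``midplane_z`` is the z of the
    bilayer midplane; ``intracellular_boundary_z`` is the z of the
    inner-leaflet headgroup plane and must lie below the midplane.
    """

    midplane_z: float = 0.0
    intracellular_boundary_z: float = -20.0

    def __post_init__(self) -> None:
        if not self.intracellular_boundary_z < self.midplane_z:
            raise ValueError(
                "degenerate membrane frame: intracellular_boundary_z "
                f"({self.intracellular_boundary_z}) must be < midplane_z "
                f"({self.midplane_z})"
            )


@dataclass(frozen=True)
class SymmetrySpec:
    """C_n rotational symmetry about the z axis through the origin.

    ``chain_cycle`` maps each chain id to its image under one positive
    (counter-clockwise) n-fold rotation; it must be a permutation whose
    n-th power is the identity.
    """

    order: int
    chain_cycle: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"symmetry order must be >= 1, got {self.order}")
        chains = set(self.chain_cycle)
        if chains and set(self.chain_cycle.values()) != chains:
            raise ValueError("chain_cycle must be a permutation of the chains")
        for start in chains:
            c = start
            for _ in range(self.order):
                c = self.chain_cycle[c]
            if c != start:
                raise ValueError(
                    f"chain_cycle applied {self.order} times is not the identity"
                )

    @classmethod
    def cyclic(cls, chains: Sequence[str]) -> "SymmetrySpec":
        """C_n spec cycling the chains in the given order (A->B->...->A)."""
        n = len(chains)
        cycle = {chains[i]: chains[(i + 1) % n] for i in range(n)}
        return cls(order=n, chain_cycle=cycle)

    def map_chain(self, chain_id: str, k: int) -> str:
        """Image of ``chain_id`` under k applications of the cycle."""
        c = chain_id
        for _ in range(k % self.order):
            c = self.chain_cycle[c]
        return c


class ProteinModel:
    """A (possibly multi-chain) protein with coordinates in the membrane frame.

    Atom data is stored column-wise in numpy arrays; :class:`AtomRecord`
    views are available through :meth:`records`.  Residue identity is
    (chain_id, residue_number).
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        symmetry: SymmetrySpec | None = None,
    ) -> None:
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        n = len(self.atom_names)
        if n == 0:
            raise ValueError("ProteinModel requires at least one atom")
        for arr in (self.elements, self.chain_ids, self.residue_numbers, self.residue_names):
            if len(arr) != n:
                raise ValueError("atom attribute arrays must have equal length")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must have shape ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        # chains in order of first appearance
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        self.chains: list[str] = list(seen)
        self.symmetry = symmetry if symmetry is not None else SymmetrySpec.cyclic(self.chains)

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[AtomRecord], symmetry: SymmetrySpec | None = None
    ) -> "ProteinModel":
        recs = list(records)
        return cls(
            atom_names=[r.atom_name for r in recs],
            elements=[r.element for r in recs],
            coords=np.array([r.coord for r in recs], dtype=float),
            chain_ids=[r.chain_id for r in recs],
            residue_numbers=[r.residue_number for r in recs],
            residue_names=[r.residue_name for r in recs],
            symmetry=symmetry,
        )

    def records(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                atom_name=self.atom_names[i],
                element=self.elements[i],
                coord=tuple(self.coords[i]),
                chain_id=self.chain_ids[i],
                residue_number=int(self.residue_numbers[i]),
                residue_name=self.residue_names[i],
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def residue_ids(self) -> list[ResidueId]:
        """Unique residues in order of first appearance."""
        out: dict[ResidueId, None] = {}
        for c, r in zip(self.chain_ids, self.residue_numbers):
            out.setdefault((c, int(r)), None)
        return list(out)

    def atom_indices_by_residue(self) -> dict[ResidueId, np.ndarray]:
        groups: dict[ResidueId, list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chain_ids, self.residue_numbers)):
            groups.setdefault((c, int(r)), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def residue_name_of(self, rid: ResidueId) -> str:
        mask = (self.chain_ids == rid[0]) & (self.residue_numbers == rid[1])
        names = self.residue_names[mask]
        if len(names) == 0:
            raise KeyError(f"no such residue: {rid}")
        return names[0]


class FrameSeries:
    """Coordinates over trajectory frames for protein atoms and lipid beads.

    Protein atoms carry (chain_id, residue_number, residue_name, atom_name)
    labels; lipid headgroup beads carry (lipid_id, bead_name).  Atom identity
    is constant across frames.  ``frame_stride_ps`` is metadata only (time
    between stored frames).
    """

    def __init__(
        self,
        protein_chain_ids: Sequence[str],
        protein_residue_numbers: Sequence[int],
        protein_residue_names: Sequence[str],
        protein_atom_names: Sequence[str],
        protein_coords: np.ndarray,
        lipid_ids: Sequence[int],
        bead_names: Sequence[str],
        bead_coords: np.ndarray,
        frame_stride_ps: float = 1000.0,
    ) -> None:
        self.protein_chain_ids = np.asarray(protein_chain_ids, dtype=object)
        self.protein_residue_numbers = np.asarray(protein_residue_numbers, dtype=int)
        self.protein_residue_names = np.asarray(protein_residue_names, dtype=object)
        self.protein_atom_names = np.asarray(protein_atom_names, dtype=object)
        self.protein_coords = np.asarray(protein_coords, dtype=float)
        self.lipid_ids = np.asarray(lipid_ids, dtype=int)
        self.bead_names = np.asarray(bead_names, dtype=object)
        self.bead_coords = np.asarray(bead_coords, dtype=float)
        self.frame_stride_ps = float(frame_stride_ps)

        if self.protein_coords.ndim != 3 or self.protein_coords.shape[2] != 3:
            raise ValueError("protein_coords must have shape (n_frames, n_atoms, 3)")
        if self.bead_coords.ndim != 3 or self.bead_coords.shape[2] != 3:
            raise ValueError("bead_coords must have shape (n_frames, n_beads, 3)")
        if self.protein_coords.shape[0] != self.bead_coords.shape[0]:
            raise ValueError("protein and bead coordinate frame counts differ")
        if self.n_frames < 1:
            raise ValueError("FrameSeries requires at least one frame")
        if self.protein_coords.shape[1] != len(self.protein_atom_names):
            raise ValueError("protein label/coordinate length mismatch")
        if self.bead_coords.shape[1] != len(self.bead_names):
            raise ValueError("bead label/coordinate length mismatch")
        if len(self.lipid_ids) != len(self.bead_names):
            raise ValueError("lipid_ids and bead_names length mismatch")

    @property
    def n_frames(self) -> int:
        return self.protein_coords.shape[0]

    def residue_ids(self) -> list[ResidueId]:
        out: dict[ResidueId, None] = {}
        for c, r in zip(self.protein_chain_ids, self.protein_residue_numbers):
            out.setdefault((c, int(r)), None)
        return list(out)

    def unique_lipid_ids(self) -> list[int]:
        out: dict[int, None] = {}
        for lid in self.lipid_ids:
            out.setdefault(int(lid), None)
        return list(out)


# ----------------------------------------------------------------------
# geometry


def rotation_matrix_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_about_z(coord: np.ndarray, k: int, order: int) -> np.ndarray:
    """Rotate coordinates by k * (360/order) degrees about the z axis.

    Accepts a single 3-vector or an (..., 3) array; the z component is
    unchanged.  ``k`` may be any integer (taken modulo ``order``).
    """
    if order < 1:
        raise ValueError(f"symmetry order must be >= 1, got {order}")
    coord = np.asarray(coord, dtype=float)
    if coord.shape[-1] != 3:
        raise ValueError("coord must have a trailing dimension of 3")
    angle = 2.0 * np.pi * (k % order) / order
    rot = rotation_matrix_z(angle)
    return coord @ rot.T


# ----------------------------------------------------------------------
# lipid-accessible residue surface


def _sidechain_mask(model: ProteinModel) -> np.ndarray:
    heavy = model.heavy_mask
    bb = np.array([n in BACKBONE_ATOM_NAMES for n in model.atom_names], dtype=bool)
    return heavy & ~bb


def _to_biotite(model: ProteinModel, indices: np.ndarray):
    import biotite.structure as struc

    arr = struc.AtomArray(len(indices))
    arr.coord = model.coords[indices]
    arr.chain_id = model.chain_ids[indices].astype("U4")
    arr.res_id = model.residue_numbers[indices]
    arr.res_name = model.residue_names[indices].astype("U5")
    arr.atom_name = model.atom_names[indices].astype("U6")
    arr.element = np.array([e.upper() for e in model.elements[indices]], dtype="U2")
    return arr


def accessible_leaflet_residues(
    model: ProteinModel,
    frame: MembraneFrame,
    sasa_rel_threshold: float = 0.20,
    probe_radius: float = 1.4,
    point_number: int = 300,
) -> set[ResidueId]:
    """Residues forming the lipid-accessible surface of the inner leaflet.

    A residue qualifies when (a) its side-chain heavy-atom centroid z lies
    within the inner-leaflet slab [intracellular_boundary_z, midplane_z] and
    (b) its relative side-chain solvent accessibility, computed on the
    isolated protein with a Shrake-Rupley probe of ``probe_radius``, is at
    least ``sasa_rel_threshold``.  Relative accessibility is the side-chain
    SASA in the intact protein divided by the side-chain SASA of the same
    residue extracted on its own (same conformation), so the measure is
    self-referential and applies to non-standard residues as well.
    Glycine-like residues without side-chain heavy atoms never qualify.
    """
    import biotite.structure as struc

    heavy_idx = np.flatnonzero(model.heavy_mask)
    if len(heavy_idx) == 0:
        raise ValueError("model has no heavy atoms")

    arr = _to_biotite(model, heavy_idx)
    sasa_full = struc.sasa(
        arr, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
    )

    sc_mask_all = _sidechain_mask(model)
    result: set[ResidueId] = set()
    for rid, idx in model.atom_indices_by_residue().items():
        sc_idx = idx[sc_mask_all[idx]]
        if len(sc_idx) == 0:
            continue
        centroid_z = model.coords[sc_idx, 2].mean()
        if not (frame.intracellular_boundary_z <= centroid_z <= frame.midplane_z):
            continue
        # SASA of the residue isolated from the rest of the protein
        res_heavy = idx[model.heavy_mask[idx]]
        iso = _to_biotite(model, res_heavy)
        sasa_iso = struc.sasa(
            iso, probe_radius=probe_radius, point_number=point_number, vdw_radii="Single"
        )
        pos_in_res = {int(a): j for j, a in enumerate(res_heavy)}
        iso_sc = sum(sasa_iso[pos_in_res[int(a)]] for a in sc_idx)
        if iso_sc <= 0.0:
            continue
        pos_in_full = {int(a): j for j, a in enumerate(heavy_idx)}
        full_sc = sum(sasa_full[pos_in_full[int(a)]] for a in sc_idx)
        if full_sc / iso_sc >= sasa_rel_threshold:
            result.add(rid)
    return result
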