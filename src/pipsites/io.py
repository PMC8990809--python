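"""Reading and writing structures, pose sets and trajectories.

All readers are backed by MDAnalysis, so the PDB/PDBQT/GRO/XTC dialects it
understands are understood here.  Coordinates are returned in angstroms
(MDAnalysis converts nm-based formats on read).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import FrameSeries, ProteinModel, SymmetrySpec

__all__ = [
    "read_structure",
    "read_pose_set",
    "read_trajectory",
    "write_structure_pdb",
    "write_pose_set_pdb",
    "write_trajectory_pdb",
    "MultiModelError",
]


class MultiModelError(ValueError):
    """Raised when a single-structure reader receives a multi-MODEL file."""


#: AutoDock atom type -> chemical element (PDBQT files carry AD types, not
#: elements).  Non-polar hydrogens are merged in AutoDock inputs, so H only
#: appears as the polar HD/HS types.
_AUTODOCK_ELEMENTS = {
    "C": "C", "A": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H", "P": "P", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "MG": "Mg", "MN": "Mn",
    "ZN": "Zn", "FE": "Fe",
}


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if name[0].isdigit() and stripped[0].upper() == "H":
        return "H"
    return stripped[0].upper()


def _universe(path: str | Path, fmt: str | None):
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kwargs = {}
    if fmt is not None:
        kwargs["format"] = fmt
        kwargs["topology_format"] = fmt
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path), **kwargs)


def _atom_arrays(u):
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    if hasattr(atoms, "icodes") and any(str(i).strip() for i in atoms.icodes):
        raise ValueError("insertion codes are not supported; renumber residues first")
    if hasattr(atoms, "elements"):
        elements = [str(e).strip() or _element_from_name(n) for e, n in zip(atoms.elements, names)]
    elif hasattr(atoms, "types"):
        elements = [
            _AUTODOCK_ELEMENTS.get(str(t).strip().upper(), _element_from_name(n))
            for t, n in zip(atoms.types, names)
        ]
    else:
        elements = [_element_from_name(n) for n in names]
    if hasattr(atoms, "chainIDs"):
        chain_ids = [str(c) if str(c).strip() else "A" for c in atoms.chainIDs]
    else:
        chain_ids = [str(s) if str(s).strip() else "A" for s in atoms.segids]
    return names, elements, chain_ids, atoms.resids.astype(int), [str(r) for r in atoms.resnames]


def read_structure(
    path: str | Path,
    fmt: str | None = None,
    symmetry: SymmetrySpec | None = None,
) -> ProteinModel:
    """Read a single-model PDB/PDBQT structure into a :class:`ProteinModel`.

    Multi-MODEL files are rejected: use :func:`read_pose_set` for docked
    pose collections or :func:`read_trajectory` for trajectories.
    """
    u = _universe(path, fmt)
    if u.trajectory.n_frames > 1:
        raise MultiModelError(
            f"{path} contains {u.trajectory.n_frames} models; "
            "use read_pose_set or read_trajectory for multi-model input"
        )
    if len(u.atoms) == 0:
        raise ValueError(f"{path}: no atoms")
    names, elements, chain_ids, resids, resnames = _atom_arrays(u)
    return ProteinModel(
        atom_names=names,
        elements=elements,
        coords=u.atoms.positions.astype(float),
        chain_ids=chain_ids,
        residue_numbers=resids,
        residue_names=resnames,
        symmetry=symmetry,
    )


def read_pose_set(path: str | Path, species: str, fmt: str | None = None):
    """Read docked poses (one pose per MODEL, AutoDock output dialect).

    Returns a list of :class:`~pipsites.poses.LigandPose`, with pose ids
    numbered 1..n in file order.  Single-model files yield one pose.
    """
    from .poses import LigandPose

    path = Path(path)
    kind = (fmt or path.suffix.lstrip(".")).lower()
    if kind == "pdbqt":
        # the PDBQT reader is single-model: split MODEL blocks ourselves
        return _read_pdbqt_pose_set(path, species)

    u = _universe(path, fmt)
    if len(u.atoms) == 0:
        raise ValueError(f"{path}: no atoms")
    names, elements, _, _, _ = _atom_arrays(u)
    poses = []
    for i, _ts in enumerate(u.trajectory):
        poses.append(
            LigandPose(
                pose_id=i + 1,
                species=species,
                atom_names=list(names),
                elements=list(elements),
                coords=u.atoms.positions.astype(float).copy(),
            )
        )
    return poses


def _read_pdbqt_pose_set(path: Path, species: str):
    import io as _io

    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    from .poses import LigandPose

    text = path.read_text()
    blocks: list[list[str]] = []
    current: list[str] = []
    in_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            blocks.append(current)
            current = []
        elif in_model or rec in ("ATOM", "HETATM", "ROOT", "ENDROOT",
                                 "BRANCH", "ENDBRANCH", "TORSDOF", "REMARK"):
            current.append(line)
    if not blocks:
        blocks = [current]
    poses = []
    for i, block in enumerate(blocks):
        stream = NamedStream(_io.StringIO("\n".join(block) + "\n"), "pose.pdbqt")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(stream, format="PDBQT", topology_format="PDBQT")
        if len(u.atoms) == 0:
            raise ValueError(f"{path}: pose {i + 1} has no atoms")
        names, elements, _, _, _ = _atom_arrays(u)
        poses.append(
            LigandPose(
                pose_id=i + 1,
                species=species,
                atom_names=list(names),
                elements=list(elements),
                coords=u.atoms.positions.astype(float).copy(),
            )
        )
    return poses


def read_trajectory(
    path: str | Path,
    lipid_resnames: Sequence[str],
    trajectory_path: str | Path | None = None,
    frame_stride_ps: float = 1000.0,
    fmt: str | None = None,
) -> FrameSeries:
    """Read a trajectory (multi-MODEL PDB, or GRO topology + XTC) into a
    :class:`FrameSeries`.

    Atoms whose residue name is in ``lipid_resnames`` become lipid headgroup
    beads tagged (lipid_id, bead_name), where lipid_id is the lipid's residue
    id; all remaining atoms are protein.  Protein atoms are ordered by
    (chain, residue) and beads by lipid id so per-group reductions are
    contiguous.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is not None:
            u = mda.Universe(str(path), str(trajectory_path))
        else:
            kwargs = {"format": fmt, "topology_format": fmt} if fmt else {}
            u = mda.Universe(str(path), **kwargs)

    names, elements, chain_ids, resids, resnames = _atom_arrays(u)
    names = np.asarray(names, dtype=object)
    chain_ids = np.asarray(chain_ids, dtype=object)
    resnames_arr = np.asarray(resnames, dtype=object)
    lipid_set = {r.upper() for r in lipid_resnames}
    is_lipid = np.array([r.upper() in lipid_set for r in resnames_arr], dtype=bool)
    if not is_lipid.any():
        raise ValueError(f"no lipid residues matching {sorted(lipid_set)} in {path}")
    if is_lipid.all():
        raise ValueError(f"no protein atoms in {path}")

    prot_idx = np.flatnonzero(~is_lipid)
    bead_idx = np.flatnonzero(is_lipid)
    prot_order = prot_idx[
        np.lexsort((resids[prot_idx], chain_ids[prot_idx].astype(str)))
    ]
    bead_order = bead_idx[np.argsort(resids[bead_idx], kind="stable")]

    n_frames = u.trajectory.n_frames
    prot_coords = np.empty((n_frames, len(prot_order), 3))
    bead_coords = np.empty((n_frames, len(bead_order), 3))
    for f, _ts in enumerate(u.trajectory):
        pos = u.atoms.positions.astype(float)
        prot_coords[f] = pos[prot_order]
        bead_coords[f] = pos[bead_order]

    return FrameSeries(
        protein_chain_ids=chain_ids[prot_order],
        protein_residue_numbers=resids[prot_order],
        protein_residue_names=resnames_arr[prot_order],
        protein_atom_names=names[prot_order],
        protein_coords=prot_coords,
        lipid_ids=resids[bead_order],
        bead_names=names[bead_order],
        bead_coords=bead_coords,
        frame_stride_ps=frame_stride_ps,
    )


# ----------------------------------------------------------------------
# writing


def _build_universe(names, resnames, resids, chain_ids, elements, n_frames=1):
    import MDAnalysis as mda

    n = len(names)
    # one residue per unique (chain, resid) run
    res_keys: list[tuple[str, int]] = []
    atom_resindex = np.empty(n, dtype=int)
    for i, key in enumerate(zip(chain_ids, resids)):
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(res_keys),
            atom_resindex=atom_resindex,
            n_segments=1,
            residue_segindex=np.zeros(len(res_keys), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(names))
        u.add_TopologyAttr("elements", list(elements))
        u.add_TopologyAttr("chainIDs", list(chain_ids))
        first_atom = [int(np.flatnonzero(atom_resindex == r)[0]) for r in range(len(res_keys))]
        u.add_TopologyAttr("resnames", [resnames[i] for i in first_atom])
        u.add_TopologyAttr("resids", [int(resids[i]) for i in first_atom])
    return u


def write_structure_pdb(model: ProteinModel, path: str | Path) -> None:
    import MDAnalysis as mda

    u = _build_universe(
        model.atom_names, model.residue_names, model.residue_numbers,
        model.chain_ids, model.elements,
    )
    u.atoms.positions = model.coords
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=False) as w:
            w.write(u.atoms)


def write_pose_set_pdb(poses, path: str | Path, resname: str | None = None) -> None:
    """Write poses as a multi-MODEL PDB (one pose per MODEL).

    All poses must share the same atom list (as AutoDock pose files do).
    """
    import MDAnalysis as mda

    if not poses:
        raise ValueError("no poses to write")
    first = poses[0]
    rn = resname or first.species[:4]
    n = len(first.atom_names)
    u = _build_universe(
        first.atom_names, [rn] * n, [1] * n, ["L"] * n, first.elements,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as w:
            for pose in poses:
                if list(pose.atom_names) != list(first.atom_names):
                    raise ValueError("poses in one file must share an atom list")
                u.atoms.positions = pose.coords
                w.write(u.atoms)


def write_trajectory_pdb(
    traj: FrameSeries, path: str | Path, lipid_resname: str = "POP3"
) -> None:
    """Write a :class:`FrameSeries` as a multi-MODEL PDB.

    Lipid beads are emitted as HET-style residues named ``lipid_resname``
    on chain "X" with the lipid id as residue number.
    """
    import MDAnalysis as mda

    n_prot = len(traj.protein_atom_names)
    n_bead = len(traj.bead_names)
    names = list(traj.protein_atom_names) + list(traj.bead_names)
    resnames = list(traj.protein_residue_names) + [lipid_resname] * n_bead
    resids = list(traj.protein_residue_numbers) + [int(l) for l in traj.lipid_ids]
    chain_ids = list(traj.protein_chain_ids) + ["X"] * n_bead
    elements = [_element_from_name(n) for n in names]
    u = _build_universe(names, resnames, resids, chain_ids, elements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = np.vstack([traj.protein_coords[f], traj.bead_coords[f]])
                w.write(u.atoms)
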