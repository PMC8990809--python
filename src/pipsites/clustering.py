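"""Centroid-proximity clustering of accepted pose vectors.

Two accepted, wedge-reduced poses are linked when their centroids are
within the cluster cutoff (default 15 A) of one another; clusters are the
single-linkage components of that relation.  The plural "centroids" is
read strictly: in the default ``all_centroids`` mode every one of the
three corresponding centroid pairs must be within the cutoff for a link;
``inositol_only`` uses just the inositol ring centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .poses import (
    LigandPose,
    PoseVector,
    compute_pose_vector,
    contact_residues,
    orientation_filter,
    reduce_to_reference_wedge,
    residue_contact_frequencies,
)
from .structures import MembraneFrame, ProteinModel, ResidueId, SymmetrySpec

logger = logging.getLogger(__name__)

__all__ = [
    "PoseCluster",
    "DockingSummary",
    "DockingConfig",
    "cluster_poses",
    "select_representative",
    "summarize_docking",
]


@dataclass
class PoseCluster:
    cluster_id: int
    member_pose_ids: tuple[int, ...]
    representative_pose_id: int
    mean_centroids: np.ndarray  # (3, 3): rows = C1, inositol, phosphate
    residue_union: frozenset[ResidueId] = frozenset()

    @property
    def size(self) -> int:
        return len(self.member_pose_ids)


@dataclass(frozen=True)
class DockingSummary:
    species: str
    state_label: str
    n_poses_total: int
    n_accepted: int
    acceptance_fraction: float
    n_clusters: int
    n_distinct_residues: int

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "state_label": self.state_label,
            "n_poses_total": self.n_poses_total,
            "n_accepted": self.n_accepted,
            "acceptance_fraction": self.acceptance_fraction,
            "n_clusters": self.n_clusters,
            "n_distinct_residues": self.n_distinct_residues,
        }


@dataclass(frozen=True)
class DockingConfig:
    """Knobs of the docking post-analysis; defaults are the published ones
    (15 A cluster cutoff, 4 A contact cutoff, four-fold symmetry handled by
    the model's SymmetrySpec) plus the package's own orientation tolerance."""

    cluster_cutoff: float = 15.0
    contact_cutoff: float = 4.0
    tolerance_deg: float = 15.0
    cluster_mode: str = "all_centroids"
    state_label: str = ""


def _pair_distances(vectors: Sequence[PoseVector], mode: str) -> np.ndarray:
    """Condensed pairwise distance for the linkage criterion.

    all_centroids: max over the three corresponding centroid distances, so
    d <= cutoff iff *each* pair is within the cutoff.  inositol_only: the
    inositol centroid distance.
    """
    if mode == "inositol_only":
        pts = np.stack([v.inositol_centroid for v in vectors])
        return pdist(pts)
    if mode != "all_centroids":
        raise ValueError(f"unknown cluster mode {mode!r}")
    d = None
    for getter in ("c1_centroid", "inositol_centroid", "phosphate_centroid"):
        pts = np.stack([getattr(v, getter) for v in vectors])
        di = pdist(pts)
        d = di if d is None else np.maximum(d, di)
    return d


def cluster_poses(
    vectors: Sequence[PoseVector],
    cutoff: float = 15.0,
    mode: str = "all_centroids",
) -> list[PoseCluster]:
    """Single-linkage clustering of wedge-reduced pose vectors.

    Clusters are ordered by descending size, ties broken by the smallest
    member pose id; representatives are medoids on the inositol centroid.
    An empty input yields an empty list.
    """
    if cutoff <= 0:
        raise ValueError("cluster cutoff must be positive")
    vectors = list(vectors)
    if not vectors:
        return []
    if len(vectors) == 1:
        labels = np.array([1])
    else:
        d = _pair_distances(vectors, mode)
        labels = fcluster(linkage(d, method="single"), t=cutoff, criterion="distance")

    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    ordered = sorted(
        groups.values(),
        key=lambda idxs: (-len(idxs), min(vectors[i].pose_id for i in idxs)),
    )
    clusters = []
    for cid, idxs in enumerate(ordered, start=1):
        members = [vectors[i] for i in idxs]
        rep = select_representative(members)
        clusters.append(
            PoseCluster(
                cluster_id=cid,
                member_pose_ids=tuple(sorted(v.pose_id for v in members)),
                representative_pose_id=rep,
                mean_centroids=np.mean([v.centroids() for v in members], axis=0),
            )
        )
    return clusters


def select_representative(members: Sequence[PoseVector]) -> int:
    """The most representative pose of a cluster: the medoid minimizing the
    summed inositol-centroid distance to all other members, ties broken by
    the smallest pose id."""
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    pts = np.stack([v.inositol_centroid for v in members])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    sums = d.sum(axis=1)
    best = min(range(len(members)), key=lambda i: (sums[i], members[i].pose_id))
    return members[best].pose_id


def summarize_docking(
    poses: Sequence[LigandPose],
    model: ProteinModel,
    frame: MembraneFrame,
    sym: SymmetrySpec | None = None,
    config: DockingConfig | None = None,
    atom_groups=None,
):
    """Run the full docking post-analysis chain.

    vectorize -> orientation filter -> wedge reduction -> centroid
    clustering -> contact identification, returning
    ``(DockingSummary, clusters, frequency_table, accepted_pairs)``.
    """
    if config is None:
        config = DockingConfig()
    if sym is None:
        sym = model.symmetry
    species = poses[0].species if poses else "NA"

    accepted: list[tuple[LigandPose, PoseVector]] = []
    for pose in poses:
        vec = compute_pose_vector(pose, atom_groups)
        ok, _phi = orientation_filter(vec, frame, tolerance_deg=config.tolerance_deg)
        if ok:
            accepted.append((pose, reduce_to_reference_wedge(vec, sym)))

    n_total, n_acc = len(poses), len(accepted)
    if n_acc == 0:
        logger.warning("no poses accepted by the orientation filter (n=%d)", n_total)
        import pandas as pd

        empty = pd.DataFrame(
            columns=["chain_id", "residue_number", "residue_name", "n_poses", "frequency_pct"]
        )
        summary = DockingSummary(
            species=species, state_label=config.state_label,
            n_poses_total=n_total, n_accepted=0, acceptance_fraction=0.0,
            n_clusters=0, n_distinct_residues=0,
        )
        return summary, [], empty, []

    contact_sets = [
        contact_residues(
            pose, model, cutoff=config.contact_cutoff,
            rotation_k=vec.wedge_rotation_k, sym_order=sym.order,
        )
        for pose, vec in accepted
    ]
    clusters = cluster_poses(
        [vec for _, vec in accepted], cutoff=config.cluster_cutoff, mode=config.cluster_mode
    )
    by_pose_id = {vec.pose_id: cs for (_, vec), cs in zip(accepted, contact_sets)}
    for cl in clusters:
        union: set[ResidueId] = set()
        for pid in cl.member_pose_ids:
            union |= by_pose_id[pid]
        cl.residue_union = frozenset(union)

    freq_table, n_distinct = residue_contact_frequencies(
        accepted, model, cutoff=config.contact_cutoff, contact_sets=contact_sets
    )
    summary = DockingSummary(
        species=species,
        state_label=config.state_label,
        n_poses_total=n_total,
        n_accepted=n_acc,
        acceptance_fraction=n_acc / n_total if n_total else 0.0,
        n_clusters=len(clusters),
        n_distinct_residues=n_distinct,
    )
    return summary, clusters, freq_table, accepted
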