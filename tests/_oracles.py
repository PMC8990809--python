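"""Independent brute-force reference implementations used to validate the
package's vectorized/linked implementations.  Everything here is written
as plainly as possible (explicit loops, no shared code with the package
beyond data containers)."""

from __future__ import annotations

import math

import numpy as np


def brute_contact_residues(pose_coords, pose_elements, model, cutoff):
    """All-pairs heavy-atom distance scan."""
    hits = set()
    for i in range(len(model.atom_names)):
        if model.elements[i].upper() == "H":
            continue
        for j in range(len(pose_coords)):
            if pose_elements[j].upper() == "H":
                continue
            d = math.dist(model.coords[i], pose_coords[j])
            if d <= cutoff:
                hits.add((model.chain_ids[i], int(model.residue_numbers[i])))
                break
    return hits


def brute_single_linkage(vectors, cutoff, mode):
    """Union-find over the explicit pairwise link condition; returns the
    partition as a set of frozensets of pose ids."""
    n = len(vectors)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(n):
        for j in range(i + 1, n):
            if mode == "inositol_only":
                linked = (
                    math.dist(vectors[i].inositol_centroid, vectors[j].inositol_centroid)
                    <= cutoff
                )
            else:
                linked = all(
                    math.dist(getattr(vectors[i], g), getattr(vectors[j], g)) <= cutoff
                    for g in ("c1_centroid", "inositol_centroid", "phosphate_centroid")
                )
            if linked:
                union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(vectors[i].pose_id)
    return {frozenset(g) for g in groups.values()}


def brute_medoid(vectors):
    """Exhaustive medoid on the inositol centroid with the smallest-id tie
    rule."""
    best = None
    for v in vectors:
        s = sum(
            math.dist(v.inositol_centroid, w.inositol_centroid) for w in vectors
        )
        key = (round(s, 9), v.pose_id)
        if best is None or key < best[0]:
            best = (key, v.pose_id)
    return best[1]


def brute_dual_cutoff(distances, r_on, r_off):
    """Hand state machine over one scripted distance series.  Returns
    (start, end) frame pairs, inclusive."""
    events = []
    active = False
    start = 0
    for t, d in enumerate(distances):
        if not active:
            if d <= r_on:
                active = True
                start = t
        else:
            if d > r_off:
                events.append((start, t - 1))
                active = False
    if active:
        events.append((start, len(distances) - 1))
    return events


def brute_occupancy(events, n_frames):
    """Frame-loop occupancy per residue (union over lipids)."""
    residues = {ev.residue for ev in events}
    out = {}
    for rid in residues:
        count = 0
        for f in range(n_frames):
            if any(
                ev.residue == rid and ev.start_frame <= f <= ev.end_frame
                for ev in events
            ):
                count += 1
        out[rid] = 100.0 * count / n_frames
    return out


def rotation_matrix_oracle(theta):
    return np.array(
        [
            [math.cos(theta), -math.sin(theta), 0.0],
            [math.sin(theta), math.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
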