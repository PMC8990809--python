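import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipsites import (
    LigandPose,
    PoseVector,
    SymmetrySpec,
    compute_pose_vector,
    contact_residues,
    make_pose_set,
    orientation_filter,
    reduce_to_reference_wedge,
    residue_contact_frequencies,
    rotate_about_z,
)
from pipsites.poses import AtomGroupMap, default_atom_groups
from _oracles import brute_contact_residues


def _pose_from(names, elements, coords, species="PI45P2", pose_id=1):
    return LigandPose(
        pose_id=pose_id, species=species, atom_names=names,
        elements=elements, coords=np.asarray(coords, float),
    )


def _vec(c1, ino, pho, pose_id=1, k=0):
    return PoseVector(pose_id, np.asarray(c1, float), np.asarray(ino, float),
                      np.asarray(pho, float), k)


class TestAtomGroupMap:
    def test_groups_nonempty_and_disjoint(self):
        with pytest.raises(ValueError):
            AtomGroupMap((), ("C1",), ("P4",))
        with pytest.raises(ValueError):
            AtomGroupMap(("C1",), ("C1", "C2"), ("P4",))

    def test_pi_falls_back_to_hydroxyl_anchor(self):
        assert default_atom_groups("PI").anchor_phosphate_atoms == ("O4",)

    def test_anchor_is_lowest_345_phosphate(self):
        assert default_atom_groups("PI45P2").anchor_phosphate_atoms[0] == "P4"
        assert default_atom_groups("PI345P3").anchor_phosphate_atoms[0] == "P3"


class TestComputePoseVector:
    def test_hexagon_centroid_is_center(self):
        angles = [math.radians(60 * j) for j in range(6)]
        names = [f"C{j+1}" for j in range(6)] + ["C1G", "P4"]
        elements = ["C"] * 6 + ["C", "P"]
        coords = [[math.cos(a), math.sin(a), 0.0] for a in angles]
        coords += [[0, 0, -3.0], [2, 0, 0]]
        groups = AtomGroupMap(("C1G",), tuple(names[:6]), ("P4",))
        vec = compute_pose_vector(_pose_from(names, elements, coords), groups)
        assert vec.inositol_centroid == pytest.approx([0, 0, 0], abs=1e-12)
        assert vec.c1_centroid == pytest.approx([0, 0, -3.0])

    def test_centroid_equals_brute_force_mean(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(6, 3)) * 4
        names = [f"C{j+1}" for j in range(6)] + ["C1G", "P4"]
        all_coords = np.vstack([coords, [[9, 9, 9], [1, 1, 1]]])
        groups = AtomGroupMap(("C1G",), tuple(names[:6]), ("P4",))
        vec = compute_pose_vector(
            _pose_from(names, ["C"] * 8, all_coords), groups
        )
        manual = [sum(coords[:, ax]) / 6 for ax in range(3)]
        assert vec.inositol_centroid == pytest.approx(manual)

    def test_missing_atom_names_group_and_atom(self):
        groups = AtomGroupMap(("C1G",), ("C1",), ("P4",))
        pose = _pose_from(["C1", "C1G"], ["C", "C"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(KeyError, match="P4.*anchor_phosphate"):
            compute_pose_vector(pose, groups)


class TestOrientationFilter:
    @pytest.mark.parametrize(
        "tail,expect_accept,expect_phi",
        [
            ((0, 0, 3.0), True, 90.0),     # straight toward the membrane
            ((0, 0, -3.0), False, -90.0),  # into the cytoplasm
            ((3.0, 0, 0), True, 0.0),      # parallel to the membrane plane
        ],
    )
    def test_reference_orientations(self, tail, expect_accept, expect_phi):
        vec = _vec(np.add([5, 5, -15], tail), [5, 5, -15], [6, 5, -15])
        ok, phi = orientation_filter(vec, tolerance_deg=15.0)
        assert ok is expect_accept
        assert phi == pytest.approx(expect_phi)

    def test_slightly_downward_within_tolerance_accepted(self):
        # elevation exactly -5 degrees
        t = np.array([math.cos(math.radians(-5)), 0.0, math.sin(math.radians(-5))]) * 4
        vec = _vec(np.add([5, 0, -15], t), [5, 0, -15], [6, 0, -15])
        ok, phi = orientation_filter(vec, tolerance_deg=15.0)
        assert ok and phi == pytest.approx(-5.0, abs=1e-9)
        ok2, _ = orientation_filter(vec, tolerance_deg=2.0)
        assert not ok2

    @given(
        st.floats(-89.0, 89.0),
        st.floats(0.0, 2 * math.pi),
        st.integers(0, 3),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_invariant_under_rotation_about_z(self, phi_deg, spin, k):
        # elevation depends only on t_z and |t|, so any rotation about z
        # leaves the decision unchanged
        t = np.array(
            [4 * math.cos(math.radians(phi_deg)) * math.cos(spin),
             4 * math.cos(math.radians(phi_deg)) * math.sin(spin),
             4 * math.sin(math.radians(phi_deg))]
        )
        ino = np.array([7.0, -2.0, -14.0])
        vec = _vec(ino + t, ino, ino + [1, 0, 0])
        rot = _vec(
            rotate_about_z(ino + t, k, 4), rotate_about_z(ino, k, 4),
            rotate_about_z(ino + [1, 0, 0], k, 4),
        )
        ok1, phi1 = orientation_filter(vec)
        ok2, phi2 = orientation_filter(rot)
        assert ok1 == ok2
        assert phi1 == pytest.approx(phi2, abs=1e-9)


class TestWedgeReduction:
    def test_already_in_wedge_unchanged(self):
        vec = _vec([11, 11, -12], [10, 10, -15], [12, 10, -15])  # azimuth 45
        out = reduce_to_reference_wedge(vec, SymmetrySpec.cyclic(list("ABCD")))
        assert out.wedge_rotation_k == 0
        assert np.allclose(out.inositol_centroid, vec.inositol_centroid)

    def test_azimuth_190_maps_to_10_with_k2(self):
        r = 20.0
        az = math.radians(190.0)
        ino = [r * math.cos(az), r * math.sin(az), -15.0]
        vec = _vec(np.add(ino, [0, 0, 3]), ino, np.add(ino, [1, 0, 0]))
        out = reduce_to_reference_wedge(vec, SymmetrySpec.cyclic(list("ABCD")))
        assert out.wedge_rotation_k == 2
        new_az = math.degrees(
            math.atan2(out.inositol_centroid[1], out.inositol_centroid[0])
        )
        assert new_az == pytest.approx(10.0, abs=1e-9)

    @given(st.floats(0.0, 359.99), st.integers(1, 8))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_idempotent_and_lands_in_wedge(self, az_deg, order):
        sym = SymmetrySpec.cyclic([chr(65 + i) for i in range(order)])
        az = math.radians(az_deg)
        ino = [15 * math.cos(az), 15 * math.sin(az), -12.0]
        vec = _vec(np.add(ino, [0, 0, 2]), ino, np.add(ino, [0.5, 0, 0]))
        once = reduce_to_reference_wedge(vec, sym)
        new_az = math.atan2(once.inositol_centroid[1], once.inositol_centroid[0])
        wedge = 2 * math.pi / order
        assert -1e-12 <= new_az % (2 * math.pi) < wedge + 1e-12
        twice = reduce_to_reference_wedge(once, sym)
        assert twice.wedge_rotation_k == once.wedge_rotation_k
        assert np.allclose(twice.inositol_centroid, once.inositol_centroid)

    def test_on_axis_rejected(self):
        vec = _vec([0, 0, -12], [0, 0, -15], [1, 0, -15])
        with pytest.raises(ValueError, match="azimuth"):
            reduce_to_reference_wedge(vec, SymmetrySpec.cyclic(list("ABCD")))


class TestContactResidues:
    def _one_atom_model(self, pos):
        from pipsites import ProteinModel

        return ProteinModel(["NZ"], ["N"], np.array([pos]), ["A"], [1], ["LYS"])

    def test_inclusive_boundary(self):
        pose = _pose_from(["O1"], ["O"], [[0.0, 0.0, 0.0]])
        near = self._one_atom_model([3.9, 0, 0])
        on = self._one_atom_model([4.0, 0, 0])
        far = self._one_atom_model([4.1, 0, 0])
        assert contact_residues(pose, near, cutoff=4.0) == {("A", 1)}
        assert contact_residues(pose, on, cutoff=4.0) == {("A", 1)}
        assert contact_residues(pose, far, cutoff=4.0) == set()

    def test_hydrogens_ignored_both_sides(self):
        pose = _pose_from(["H1", "O1"], ["H", "O"], [[3.0, 0, 0], [50, 0, 0]])
        model = self._one_atom_model([0.0, 0.0, 0.0])
        assert contact_residues(pose, model, cutoff=4.0) == set()

    def test_matches_brute_force_on_random_instances(self, toy_model):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 20
            coords = rng.uniform(-30, 30, size=(n, 3))
            elements = ["C"] * (n - 3) + ["H"] * 3
            pose = _pose_from([f"X{i}" for i in range(n)], elements, coords)
            cutoff = rng.uniform(3.0, 6.0)
            got = contact_residues(pose, toy_model, cutoff=cutoff)
            expected = brute_contact_residues(coords, elements, toy_model, cutoff)
            assert got == expected

    def test_monotone_in_cutoff(self, toy_model):
        rng = np.random.default_rng(23)
        coords = rng.uniform(-28, 28, size=(15, 3))
        pose = _pose_from([f"X{i}" for i in range(15)], ["C"] * 15, coords)
        small = contact_residues(pose, toy_model, cutoff=3.5)
        large = contact_residues(pose, toy_model, cutoff=6.0)
        assert small <= large


class TestContactFrequencies:
    def test_simple_fractions(self, toy_model):
        # hand-built contact sets: residue X in 1 of 2 poses, Y in both
        pose = _pose_from(["O1"], ["O"], [[0, 0, 0]])
        vecs = [_vec([0, 0, 1], [0, 0, 0], [1, 0, 0], pose_id=i) for i in (1, 2)]
        sets = [{("A", 1), ("A", 2)}, {("A", 2)}]
        table, n_distinct = residue_contact_frequencies(
            [(pose, v) for v in vecs], toy_model, contact_sets=sets
        )
        assert n_distinct == 2
        by_res = {
            (r.chain_id, r.residue_number): r.frequency_pct for r in table.itertuples()
        }
        assert by_res[("A", 2)] == pytest.approx(100.0)
        assert by_res[("A", 1)] == pytest.approx(50.0)

    def test_planted_probabilities_recovered(self, toy_model):
        probs = {("A", 1): 0.8, ("B", 1): 0.3}
        poses, truth = make_pose_set(
            toy_model, [[40.0, 12.0, -15.0]], n_per_center=400,
            scatter_sigma=1.0, frac_misoriented=0.0, seed=29, contact_probs=probs,
        )
        pairs = [(p, compute_pose_vector(p)) for p in poses]
        table, _ = residue_contact_frequencies(pairs, toy_model)
        by_res = {
            (r.chain_id, r.residue_number): r.frequency_pct for r in table.itertuples()
        }
        assert by_res[("A", 1)] == pytest.approx(80.0, abs=5.0)
        assert by_res[("B", 1)] == pytest.approx(30.0, abs=5.0)

    def test_frequencies_bounded(self, toy_model, two_center_poses):
        from pipsites import MembraneFrame, summarize_docking

        poses, _ = two_center_poses
        _, _, table, _ = summarize_docking(poses, toy_model, MembraneFrame())
        assert ((table.frequency_pct > 0) & (table.frequency_pct <= 100)).all()

    def test_empty_accepted_set_rejected(self, toy_model):
        with pytest.raises(ValueError):
            residue_contact_frequencies([], toy_model)
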