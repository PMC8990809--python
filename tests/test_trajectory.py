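import numpy as np
import pytest

from pipsites import (
    ContactEvent,
    FrameSeries,
    SiteDef,
    cluster_binding_sites,
    density_map,
    dual_cutoff_events,
    make_dwell_trajectory,
    residence_times,
    residue_occupancy,
    site_occupancy,
)
from _oracles import brute_dual_cutoff, brute_occupancy


def _scripted_traj(distances):
    """One residue particle at the origin, one lipid bead at (d, 0, 0)."""
    d = np.asarray(distances, float)
    F = len(d)
    prot = np.zeros((F, 1, 3))
    beads = np.zeros((F, 1, 3))
    beads[:, 0, 0] = d
    return FrameSeries(
        protein_chain_ids=["A"], protein_residue_numbers=[1],
        protein_residue_names=["LYS"], protein_atom_names=["NZ"],
        protein_coords=prot, lipid_ids=[1], bead_names=["PO4"],
        bead_coords=beads, frame_stride_ps=1000.0,
    )


class TestDualCutoffEvents:
    def test_scripted_entry_persist_exit(self):
        # 0.4 nm frames 10-19, 0.7 nm frames 20-24, 0.9 nm frame 25+
        d = np.full(30, 9.5)
        d[10:20] = 4.0
        d[20:25] = 7.0
        d[25:] = 9.0
        events = dual_cutoff_events(_scripted_traj(d), 0.5, 0.8)
        assert [(e.start_frame, e.end_frame) for e in events] == [(10, 24)]

    def test_never_initiated_between_cutoffs(self):
        events = dual_cutoff_events(_scripted_traj(np.full(50, 6.0)), 0.5, 0.8)
        assert events == []

    def test_contact_through_all_frames(self):
        events = dual_cutoff_events(_scripted_traj(np.full(100, 3.0)), 0.5, 0.8)
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 99)]

    def test_matches_state_machine_oracle_on_random_walks(self):
        rng = np.random.default_rng(61)
        for _ in range(30):
            F = int(rng.integers(5, 200))
            d = np.clip(np.cumsum(rng.normal(0, 1.5, F)) + 7.0, 1.0, 14.0)
            events = dual_cutoff_events(_scripted_traj(d), 0.5, 0.8)
            assert [(e.start_frame, e.end_frame) for e in events] == \
                brute_dual_cutoff(d, 5.0, 8.0)

    def test_equal_cutoffs_reduce_to_single_threshold(self):
        rng = np.random.default_rng(67)
        d = np.clip(np.cumsum(rng.normal(0, 1.5, 150)) + 7.0, 1.0, 14.0)
        events = dual_cutoff_events(_scripted_traj(d), 0.6, 0.6)
        # naive thresholding oracle: maximal runs of d <= 6.0
        inside = d <= 6.0
        runs = []
        start = None
        for f, flag in enumerate(inside):
            if flag and start is None:
                start = f
            elif not flag and start is not None:
                runs.append((start, f - 1))
                start = None
        if start is not None:
            runs.append((start, len(d) - 1))
        assert [(e.start_frame, e.end_frame) for e in events] == runs

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            dual_cutoff_events(_scripted_traj([5.0]), 0.8, 0.5)


class TestResidueOccupancy:
    def test_fifteen_of_hundred_frames(self):
        events = [ContactEvent(1, ("A", 1), 10, 24)]
        table = residue_occupancy(events, 100)
        assert table.occupancy_pct.iloc[0] == pytest.approx(15.0)

    def test_overlapping_lipids_count_once(self):
        events = [
            ContactEvent(1, ("A", 1), 0, 99),
            ContactEvent(2, ("A", 1), 0, 99),
        ]
        table = residue_occupancy(events, 100)
        assert table.occupancy_pct.iloc[0] == pytest.approx(100.0)

    def test_no_events_empty_table(self):
        assert len(residue_occupancy([], 100)) == 0

    def test_matches_frame_loop_oracle_and_bounds(self):
        rng = np.random.default_rng(71)
        for _ in range(10):
            F = int(rng.integers(20, 120))
            events = []
            for lid in range(1, 4):
                for rid in [("A", 1), ("A", 2), ("B", 5)]:
                    t = 0
                    while t < F:
                        span = int(rng.integers(1, 15))
                        end = min(t + span - 1, F - 1)
                        if rng.random() < 0.5:
                            events.append(ContactEvent(lid, rid, t, end))
                        t = end + 2
            table = residue_occupancy(events, F)
            expected = brute_occupancy(events, F)
            assert ((table.occupancy_pct >= 0) & (table.occupancy_pct <= 100)).all()
            for row in table.itertuples():
                assert row.occupancy_pct == pytest.approx(
                    expected[(row.chain_id, row.residue_number)]
                )

    def test_monotone_in_outer_cutoff(self):
        rng = np.random.default_rng(73)
        d = np.clip(np.cumsum(rng.normal(0, 1.2, 300)) + 6.5, 1.0, 13.0)
        traj = _scripted_traj(d)
        occ = {}
        for r_off in (0.6, 0.8, 1.0):
            table = residue_occupancy(dual_cutoff_events(traj, 0.5, r_off), 300)
            occ[r_off] = table.occupancy_pct.iloc[0] if len(table) else 0.0
        assert occ[0.6] <= occ[0.8] <= occ[1.0]


class TestResidenceTimes:
    def test_single_event_duration(self):
        t = residence_times([ContactEvent(1, ("A", 1), 0, 14)], 1000.0)
        assert t.mean_duration_ps.iloc[0] == 15000.0
        assert t.max_duration_ps.iloc[0] == 15000.0

    def test_mean_of_two_events(self):
        events = [ContactEvent(1, ("A", 1), 0, 9), ContactEvent(1, ("A", 1), 20, 49)]
        t = residence_times(events, 1000.0)
        assert t.mean_duration_ps.iloc[0] == pytest.approx(20000.0)
        assert t.n_events.iloc[0] == 2

    def test_planted_geometric_dwell_mean_recovered(self, toy_model):
        # four independent lipids dwelling on long side chains
        sites = [
            SiteDef(residues=((c, 7),), dwell_mean_frames=50.0)
            for c in "ABCD"
        ]
        traj, truth = make_dwell_trajectory(toy_model, sites, n_frames=6000, seed=79)
        events = dual_cutoff_events(traj, 0.5, 0.8)
        assert len(events) >= 200
        mean = np.mean([e.duration_frames for e in events])
        assert mean == pytest.approx(50.0, rel=0.15)
        # detected events correspond one-to-one to the schedule
        assert len(events) == len(truth.schedules)


class TestBindingSites:
    def test_disjoint_lipids_make_two_sites(self):
        events = [
            ContactEvent(1, ("A", 1), 0, 49), ContactEvent(1, ("A", 2), 0, 49),
            ContactEvent(2, ("B", 1), 0, 49), ContactEvent(2, ("B", 2), 0, 49),
        ]
        sites, singles = cluster_binding_sites(events, 100)
        assert {frozenset(s.residues) for s in sites} == {
            frozenset({("A", 1), ("A", 2)}), frozenset({("B", 1), ("B", 2)}),
        }
        assert singles == []

    def test_parked_lipid_joins_all_residues(self):
        events = [ContactEvent(1, ("A", r), 0, 99) for r in range(1, 5)]
        sites, _ = cluster_binding_sites(events, 100)
        assert len(sites) == 1 and len(sites[0].residues) == 4

    def test_below_threshold_co_contact_stays_split(self):
        # lipid 1 bridges the two residues for only 2% of frames
        events = [
            ContactEvent(1, ("A", 1), 0, 49),
            ContactEvent(1, ("A", 2), 48, 97),
            ContactEvent(2, ("A", 2), 0, 40),
        ]
        sites, singles = cluster_binding_sites(events, 100, min_edge_pct=5.0)
        assert sites == []
        assert set(singles) == {("A", 1), ("A", 2)}

    def test_planted_two_site_recovery(self, toy_model, dwell_fixture):
        traj, truth = dwell_fixture
        events = dual_cutoff_events(traj, 0.5, 0.8)
        sites, singles = cluster_binding_sites(events, traj.n_frames)
        got = {frozenset(s.residues) for s in sites}
        planted = {frozenset(rs) for rs in truth.site_residues[:2]}
        assert got == planted  # the 0%-occupancy site produces no events
        assert singles == []

    def test_no_events(self):
        assert cluster_binding_sites([], 100) == ([], [])


class TestSiteOccupancy:
    def test_disjoint_halves_union_to_full(self):
        events = [
            ContactEvent(1, ("A", 1), 0, 49),
            ContactEvent(2, ("A", 2), 50, 99),
        ]
        assert site_occupancy([("A", 1), ("A", 2)], events, 100) == 100.0

    def test_never_contacted_site_is_zero(self):
        assert site_occupancy([("C", 9)], [ContactEvent(1, ("A", 1), 0, 9)], 100) == 0.0

    def test_ninety_of_hundred_frames(self):
        events = [ContactEvent(1, ("A", 1), 5, 94)]
        assert site_occupancy([("A", 1)], events, 100) == pytest.approx(90.0)

    def test_site_occupancy_at_least_max_member(self, dwell_fixture):
        traj, _ = dwell_fixture
        events = dual_cutoff_events(traj, 0.5, 0.8)
        sites, _ = cluster_binding_sites(events, traj.n_frames)
        for s in sites:
            per_res = s.top_residue_occupancies.occupancy_pct.max()
            assert s.occupancy_pct >= per_res - 1e-9


class TestDensityMap:
    def test_static_lipid_single_cell(self):
        F = 20
        prot = np.zeros((F, 1, 3))
        beads = np.tile(np.array([[3.0, 4.0, -12.0]]), (F, 1, 1))
        traj = FrameSeries(["A"], [1], ["LYS"], ["NZ"], prot, [1], ["PO4"],
                           beads, 1000.0)
        dm = density_map(traj, grid_spacing=2.0)
        assert dm.total_mass() == pytest.approx(1.0)
        assert np.count_nonzero(dm.counts) == 1
        assert dm.counts.max() == pytest.approx(1.0)

    def test_mass_conservation(self, dwell_fixture):
        traj, _ = dwell_fixture
        dm = density_map(traj, grid_spacing=3.0, leaflet="both")
        total_obs = dm.total_mass() * traj.n_frames
        assert total_obs == pytest.approx(len(traj.bead_names) * traj.n_frames)

    def test_uniform_positions_within_4_sigma(self):
        rng = np.random.default_rng(83)
        F, B = 100, 100  # 10^4 observations
        prot = np.zeros((F, 1, 3))
        beads = np.empty((F, B, 3))
        beads[..., 0] = rng.uniform(0, 40, (F, B))
        beads[..., 1] = rng.uniform(0, 40, (F, B))
        beads[..., 2] = -10.0
        traj = FrameSeries(["A"], [1], ["GLY"], ["CA"], prot,
                           list(range(1, B + 1)), ["PO4"] * B, beads, 1000.0)
        dm = density_map(traj, grid_spacing=10.0)
        n_cells = dm.counts.size
        n_obs = F * B
        p = 1.0 / n_cells
        expect = n_obs * p / F
        sigma = np.sqrt(n_obs * p * (1 - p)) / F
        assert np.abs(dm.counts - expect).max() <= 4 * sigma

    def test_leaflet_filter_and_errors(self, dwell_fixture):
        traj, _ = dwell_fixture
        inner = density_map(traj, grid_spacing=3.0, leaflet="inner")
        both = density_map(traj, grid_spacing=3.0, leaflet="both")
        assert inner.total_mass() <= both.total_mass() + 1e-9
        with pytest.raises(ValueError):
            density_map(traj, grid_spacing=0.0)

    def test_save_text_round_trip(self, tmp_path, dwell_fixture):
        import json

        traj, _ = dwell_fixture
        dm = density_map(traj, grid_spacing=3.0)
        dm.save_text(tmp_path / "d.txt", tmp_path / "d.json")
        counts = np.loadtxt(tmp_path / "d.txt")
        header = json.loads((tmp_path / "d.json").read_text())
        assert counts.reshape(dm.counts.shape) == pytest.approx(dm.counts)
        assert header["spacing"] == 3.0


class TestFullAnalysisRotationInvariance:
    def test_occupancy_invariant_under_global_z_rotation(self, toy_model, dwell_fixture):
        from pipsites.structures import rotate_about_z

        traj, _ = dwell_fixture
        rng = np.random.default_rng(89)
        prot = traj.protein_coords.copy()
        beads = traj.bead_coords.copy()
        for f in range(traj.n_frames):
            k = int(rng.integers(0, 4))
            prot[f] = rotate_about_z(prot[f], k, 4)
            beads[f] = rotate_about_z(beads[f], k, 4)
        rotated = FrameSeries(
            traj.protein_chain_ids, traj.protein_residue_numbers,
            traj.protein_residue_names, traj.protein_atom_names, prot,
            traj.lipid_ids, traj.bead_names, beads, traj.frame_stride_ps,
        )
        occ_a = residue_occupancy(dual_cutoff_events(traj, 0.5, 0.8), traj.n_frames)
        occ_b = residue_occupancy(dual_cutoff_events(rotated, 0.5, 0.8), traj.n_frames)
        assert occ_a.equals(occ_b)
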