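"""State labeling and event extraction: hand-traceable cases, ground-truth
oracle on the toy trajectory, and hysteresis invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gasbind.labeling import (
    BOUND,
    INTERMEDIATE,
    UNBOUND,
    Event,
    SiteDefinition,
    StateSeries,
    events_to_passage_times,
    extract_events,
    label_frames,
    read_events_csv,
    surface_crossing_point,
    write_events_csv,
)


def _universe(ligand_xyz, box=200.0, n_frames=1):
    """Tiny topology: Ni + Fe 2 Å apart, one S bead, one ligand atom."""
    import MDAnalysis as mda

    u = mda.Universe.empty(
        n_atoms=4, n_residues=4, atom_resindex=np.arange(4), trajectory=True
    )
    u.add_TopologyAttr("name", ["NI", "FE", "S1", "LIG"])
    u.add_TopologyAttr("resname", ["PRO", "PRO", "PRO", "LIG"])
    u.add_TopologyAttr("resid", [1, 2, 3, 4])
    u.add_TopologyAttr("masses", [58.7, 55.8, 32.1, 2.0])
    frames = np.empty((n_frames, 4, 3), dtype=np.float32)
    protein = np.array(
        [[99.0, 100.0, 100.0], [101.0, 100.0, 100.0], [100.0, 110.0, 100.0]]
    )
    lig = np.atleast_2d(np.asarray(ligand_xyz, dtype=float))
    for f in range(n_frames):
        frames[f, :3] = protein
        frames[f, 3] = lig[f if len(lig) > 1 else 0]
    u.load_new(frames, dt=1000.0)  # 1 ns frames
    for ts in u.trajectory:
        ts.dimensions = [box, box, box, 90, 90, 90]
    u.trajectory.rewind()
    return u


SITE = SiteDefinition(
    site_atoms="name NI FE",
    anchor_pair=("name NI", "name FE"),
    bound_cutoff=5.0,
    interface_cutoff=3.0,
)


class TestLabelFrames:
    def test_ligand_at_site_center_is_bound(self):
        u = _universe([100.0, 100.0, 100.0])
        (s,) = label_frames(u, SITE, protein_selection="resname PRO")
        assert s.labels[0] == BOUND

    def test_far_ligand_is_unbound(self):
        u = _universe([20.0, 20.0, 20.0])
        (s,) = label_frames(u, SITE, protein_selection="resname PRO")
        assert s.labels[0] == UNBOUND

    def test_near_site_but_far_from_interface_is_intermediate(self):
        # 4.5 Å below the S bead keeps protein contact, ~10.6 Å from the
        # Ni-Fe midpoint: inside neither the bound nor the unbound region
        u = _universe([100.0, 106.5, 100.0])
        (s,) = label_frames(u, SITE, protein_selection="resname PRO")
        assert s.labels[0] == INTERMEDIATE

    def test_hand_computed_distances_on_two_frames(self):
        # frame 0 bound at midpoint, frame 1 unbound far away
        u = _universe([[100.0, 100.0, 100.0], [150.0, 150.0, 150.0]], n_frames=2)
        (s,) = label_frames(u, SITE, protein_selection="resname PRO")
        np.testing.assert_array_equal(s.labels, [BOUND, UNBOUND])
        np.testing.assert_allclose(s.positions[0], [100.0, 100.0, 100.0])

    def test_minimum_image_convention(self):
        # ligand near the opposite box face is close through the boundary
        u = _universe([199.0, 100.0, 100.0], box=200.0)
        (s,) = label_frames(u, SITE, protein_selection="resname PRO")
        # wrapped distance to NI at x=99 is 100 A -> still no contact, but
        # to the site COM it is far: unbound, and no crash from wrapping
        assert s.labels[0] == UNBOUND

    def test_empty_selection_errors(self):
        u = _universe([100.0, 100.0, 100.0])
        with pytest.raises(ValueError, match="empty"):
            label_frames(u, SITE, ligand_selection="resname XXX",
                         protein_selection="resname PRO")
        bad = SiteDefinition(site_atoms="name ZZ", anchor_pair=("name NI", "name FE"))
        with pytest.raises(ValueError, match="empty"):
            label_frames(u, bad, protein_selection="resname PRO")

    def test_missing_box_errors_with_frame(self):
        u = _universe([100.0, 100.0, 100.0])
        for ts in u.trajectory:
            ts.dimensions = None
        u.trajectory.rewind()
        with pytest.raises(ValueError, match="frame 0"):
            label_frames(u, SITE, protein_selection="resname PRO")


def _series(codes, dt=1.0, positions=None, outside=None):
    labels = {"U": UNBOUND, "I": INTERMEDIATE, "B": BOUND}
    arr = np.array([labels[c] for c in codes], dtype=np.int8)
    return StateSeries(
        ligand_id=0,
        labels=arr,
        frame_times=np.arange(len(arr)) * dt,
        positions=positions,
        outside=outside,
    )


class TestExtractEvents:
    def test_hand_traceable_sequence(self):
        events = extract_events(_series("UUIBBIU"), min_dwell=1)
        assert [e.kind for e in events] == ["binding", "unbinding"]
        binding, unbinding = events
        assert binding.passage_time == pytest.approx(3.0)  # frames 0 -> 3
        assert unbinding.passage_time == pytest.approx(3.0)  # frames 3 -> 6

    def test_all_unbound_gives_no_events(self):
        assert extract_events(_series("UUUUU")) == []

    def test_all_intermediate_gives_no_events(self):
        assert extract_events(_series("IIIII")) == []

    def test_min_dwell_suppresses_recrossing(self):
        # single-frame bound blip does not qualify at min_dwell=2
        assert len(extract_events(_series("UUBUU"), min_dwell=1)) == 2
        assert extract_events(_series("UUBUU"), min_dwell=2) == []

    def test_fpt_reference_frames(self):
        # second binding measured from the completing unbinding frame
        events = extract_events(_series("UBBUUBB"), min_dwell=1)
        kinds = [e.kind for e in events]
        assert kinds == ["binding", "unbinding", "binding"]
        assert events[0].passage_time == pytest.approx(1.0)  # 0 -> 1
        assert events[1].passage_time == pytest.approx(2.0)  # 1 -> 3
        assert events[2].passage_time == pytest.approx(2.0)  # 3 -> 5

    def test_initially_bound_ligand_contributes_no_orphan_event(self):
        events = extract_events(_series("BBUU"), min_dwell=1)
        assert events == []

    def test_naive_transition_count_without_intermediates(self):
        codes = "UBUBUBUB"
        events = extract_events(_series(codes), min_dwell=1)
        assert len(events) == 7  # every transition commits

    def test_ground_truth_oracle(self, toy_trajectory, toy_series):
        """Event extraction reproduces the simulator's recorded events."""
        events = [ev for s in toy_series for ev in extract_events(s)]
        got = sorted((e.ligand_id, e.kind, e.end_frame) for e in events)
        expected = sorted(
            (e.ligand, e.kind, e.frame)
            for e in toy_trajectory.ground_truth_events
        )
        assert got == expected

    def test_passage_times_match_ground_truth(self, toy_trajectory, toy_events):
        from gasbind.synthetic import ground_truth_passage_times

        gt_fpts, gt_res = ground_truth_passage_times(toy_trajectory)
        fpts, res = events_to_passage_times(toy_events)
        np.testing.assert_allclose(np.sort(fpts), np.sort(gt_fpts))
        np.testing.assert_allclose(np.sort(res), np.sort(gt_res))


LABEL_SEQS = st.lists(
    st.sampled_from([UNBOUND, INTERMEDIATE, BOUND]), min_size=2, max_size=60
)


class TestHysteresisInvariants:
    @settings(max_examples=200, deadline=None)
    @given(LABEL_SEQS)
    def test_events_alternate_per_ligand(self, codes):
        s = StateSeries(0, np.array(codes, dtype=np.int8), np.arange(len(codes), dtype=float))
        events = extract_events(s, min_dwell=1)
        kinds = [e.kind for e in events]
        for a, b in zip(kinds, kinds[1:]):
            assert a != b
        n_bind = kinds.count("binding")
        n_unbind = kinds.count("unbinding")
        assert abs(n_bind - n_unbind) <= 1

    @settings(max_examples=200, deadline=None)
    @given(LABEL_SEQS, st.integers(min_value=1, max_value=4))
    def test_raising_min_dwell_never_adds_events(self, codes, dwell):
        s = StateSeries(0, np.array(codes, dtype=np.int8), np.arange(len(codes), dtype=float))
        n_low = len(extract_events(s, min_dwell=dwell))
        n_high = len(extract_events(s, min_dwell=dwell + 1))
        assert n_high <= n_low


class TestSurfaceCrossing:
    def test_trace_entirely_outside_is_flagged(self):
        e = Event(
            kind="binding",
            ligand_id=0,
            replica_id=0,
            start_frame=0,
            end_frame=5,
            passage_time=1.0,
            crossing_trace=np.zeros((4, 3)),
            crossing_outside=np.array([True, True, True, True]),
        )
        assert surface_crossing_point(e) is None

    def test_monotone_inward_trace_returns_last_outside_point(self):
        trace = np.array([[10.0, 0, 0], [8.0, 0, 0], [6.0, 0, 0], [4.0, 0, 0]])
        e = Event(
            kind="binding",
            ligand_id=0,
            replica_id=0,
            start_frame=0,
            end_frame=5,
            passage_time=1.0,
            crossing_trace=trace,
            crossing_outside=np.array([True, True, False, False]),
        )
        np.testing.assert_allclose(surface_crossing_point(e), [8.0, 0, 0])
        # same trace via an explicit surface definition
        np.testing.assert_allclose(
            surface_crossing_point(e, surface_def=lambda p: p[0] > 7.0),
            [8.0, 0, 0],
        )

    def test_unbinding_returns_first_outside_point(self):
        trace = np.array([[4.0, 0, 0], [6.0, 0, 0], [8.0, 0, 0]])
        e = Event(
            kind="unbinding",
            ligand_id=0,
            replica_id=0,
            start_frame=0,
            end_frame=5,
            passage_time=1.0,
            crossing_trace=trace,
            crossing_outside=np.array([False, False, True]),
        )
        np.testing.assert_allclose(surface_crossing_point(e), [8.0, 0, 0])

    def test_toy_crossing_points_lie_in_recorded_channel_mouth(
        self, toy_trajectory, toy_events
    ):
        sys_ = toy_trajectory.system
        gt = {
            (e.ligand, e.kind, e.frame): e.channel
            for e in toy_trajectory.ground_truth_events
        }
        checked = 0
        for e in toy_events:
            point = surface_crossing_point(e)
            if point is None:
                continue
            channel = gt[(e.ligand_id, e.kind, e.end_frame)]
            axis = sys_.channels[channel][0]
            disp = sys_.displacement(np.asarray(point) / 10.0)[0]
            ray = np.linalg.norm(disp - np.dot(disp, axis) * axis)
            assert ray < 3 * sys_.channels[channel][1]
            checked += 1
        assert checked > 10


def test_events_csv_roundtrip(tmp_path, toy_events):
    path = tmp_path / "events.csv"
    write_events_csv(toy_events, path)
    back = read_events_csv(path)
    assert len(back) == len(toy_events)
    for a, b in zip(back, toy_events):
        assert a.kind == b.kind
        assert a.ligand_id == b.ligand_id
        assert a.end_frame == b.end_frame
        assert a.passage_time == pytest.approx(b.passage_time)


def test_event_validation():
    with pytest.raises(ValueError):
        Event("binding", 0, 0, 5, 5, 1.0)
    with pytest.raises(ValueError):
        Event("adsorption", 0, 0, 0, 5, 1.0)
    with pytest.raises(ValueError):
        Event("binding", 0, 0, 0, 5, -1.0)
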