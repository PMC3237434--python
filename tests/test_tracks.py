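"""Wound-edge migration metrics: conventions, invariances, group summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import micromot as mm
from micromot.errors import TrackError
from micromot.synth import SyntheticParams, simulate_tracks

FRAME = mm.WoundFrame(edge_point=(0.0, 0.0), wound_normal=(0.0, 1.0))


def make_track(positions, dt=1.0, cell_id="c"):
    positions = np.asarray(positions, float)
    return mm.CellTrack(cell_id, np.arange(len(positions)) * dt, positions)


class TestConventions:
    def test_straight_perpendicular_track(self):
        """(0,0)->(0,10) over 10 min: displacement 10, speed 1, angle 90, persistence 1."""
        track = make_track([[0, 0], [0, 5], [0, 10]], dt=5.0)
        m = mm.compute_track_metrics(track, FRAME)
        assert m.displacement_into_wound_um == pytest.approx(10.0)
        assert m.speed_um_per_min == pytest.approx(1.0)
        assert m.angle_deg == 90.0
        assert m.persistence == 1.0

    def test_closed_square_loop(self):
        track = make_track([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]])
        m = mm.compute_track_metrics(track, FRAME)
        assert m.net_displacement_um == 0.0
        assert m.path_length_um == pytest.approx(40.0)
        assert m.persistence == 0.0
        assert math.isnan(m.angle_deg)

    def test_retreating_cell_has_negative_signed_displacement(self):
        track = make_track([[0, 0], [0, -8]])
        m = mm.compute_track_metrics(track, FRAME)
        assert m.displacement_into_wound_um == pytest.approx(-8.0)
        assert m.angle_deg == pytest.approx(90.0)  # perpendicular regardless of sidedness

    def test_along_edge_track_has_zero_signed_displacement(self):
        track = make_track([[0, 0], [7, 0]])
        m = mm.compute_track_metrics(track, FRAME)
        assert m.displacement_into_wound_um == pytest.approx(0.0)
        assert m.angle_deg in (pytest.approx(0.0), pytest.approx(180.0))


class TestValidation:
    def test_too_short_track_raises(self):
        with pytest.raises(TrackError):
            mm.CellTrack("c", np.array([0.0]), np.zeros((1, 2)))

    def test_non_increasing_times_raise(self):
        with pytest.raises(TrackError):
            mm.CellTrack("c", np.array([0.0, 5.0, 5.0]), np.zeros((3, 2)))

    def test_zero_normal_raises(self):
        with pytest.raises(TrackError):
            mm.WoundFrame(edge_point=(0, 0), wound_normal=(0, 0))

    def test_shape_mismatch_raises(self):
        with pytest.raises(TrackError):
            mm.CellTrack("c", np.array([0.0, 1.0]), np.zeros((3, 2)))


@st.composite
def random_tracks(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    coords = draw(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
            ),
            min_size=n,
            max_size=n,
        )
    )
    return make_track(coords, dt=3.0)


class TestInvariances:
    @given(track=random_tracks())
    def test_persistence_bounded_by_one(self, track):
        m = mm.compute_track_metrics(track, FRAME)
        assert math.isnan(m.persistence) or 0.0 <= m.persistence <= 1.0

    @given(
        track=random_tracks(),
        theta=st.floats(0, 2 * math.pi),
        shift=st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    )
    def test_rigid_motion_applied_jointly_preserves_metrics(self, track, theta, shift):
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = mm.CellTrack(
            track.cell_id, track.times_min, track.positions_um @ R.T + np.asarray(shift)
        )
        frame2 = mm.WoundFrame(
            edge_point=tuple(R @ np.array(FRAME.edge_point) + shift),
            wound_normal=tuple(R @ np.array(FRAME.wound_normal)),
        )
        m0 = mm.compute_track_metrics(track, FRAME)
        m1 = mm.compute_track_metrics(moved, frame2)
        for name in ("path_length_um", "net_displacement_um", "displacement_into_wound_um",
                     "speed_um_per_min", "angle_deg", "persistence"):
            a, b = getattr(m0, name), getattr(m1, name)
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-7)

    @given(track=random_tracks())
    def test_time_rescaling_halves_speed_only(self, track):
        slow = mm.CellTrack(track.cell_id, track.times_min * 2.0, track.positions_um)
        m0 = mm.compute_track_metrics(track, FRAME)
        m1 = mm.compute_track_metrics(slow, FRAME)
        assert m1.speed_um_per_min == pytest.approx(m0.speed_um_per_min / 2.0)
        for name in ("path_length_um", "net_displacement_um", "persistence", "angle_deg"):
            a, b = getattr(m0, name), getattr(m1, name)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestStepAngles:
    def test_per_step_variant(self):
        from micromot.tracks import step_angles_deg

        track = make_track([[0, 0], [0, 5], [5, 5]])
        angles = step_angles_deg(track, FRAME)
        assert angles[0] == pytest.approx(90.0)
        assert angles[1] in (pytest.approx(0.0), pytest.approx(180.0))


class TestGroupSummary:
    def test_mean_of_persistences(self):
        t1 = make_track([[0, 0], [0, 10]])
        t2 = make_track([[0, 0], [5, 0], [0, 0]])
        summary = mm.summarize_group(
            [mm.compute_track_metrics(t, FRAME) for t in (t1, t2)], condition="x"
        )
        row = summary[summary.metric == "persistence"].iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["n"] == 2

    def test_single_track_flags_undefined_dispersion(self):
        m = mm.compute_track_metrics(make_track([[0, 0], [0, 10]]), FRAME)
        summary = mm.summarize_group([m])
        assert summary["sd"].isna().all()
        assert (summary["n"] == 1).all()

    def test_empty_group_raises(self):
        with pytest.raises(TrackError):
            mm.summarize_group([])

    def test_deterministic_metric_ordering(self):
        m = mm.compute_track_metrics(make_track([[0, 0], [0, 10]]), FRAME)
        assert list(mm.summarize_group([m])["metric"]) == list(
            __import__("micromot.tracks", fromlist=["METRIC_NAMES"]).METRIC_NAMES
        )


class TestSimulator:
    def test_high_persistence_and_bias_approach_straight_perpendicular(self):
        params = SyntheticParams(seed=1, track_persistence=1.0, track_bias=1.0,
                                 track_kappa=500.0)
        tracks, _ = simulate_tracks(params, 10, FRAME)
        ms = [mm.compute_track_metrics(t, FRAME) for t in tracks]
        assert np.mean([m.persistence for m in ms]) > 0.98
        assert np.mean([m.angle_deg for m in ms]) == pytest.approx(90.0, abs=2.0)

    def test_persistence_setting_orders_group_means(self):
        for seed in range(5):
            frame = FRAME
            hi, _ = simulate_tracks(
                SyntheticParams(seed=seed, track_persistence=0.95, track_bias=0.0,
                                track_kappa=50.0), 15, frame)
            lo, _ = simulate_tracks(
                SyntheticParams(seed=seed + 100, track_persistence=0.0, track_bias=0.0),
                15, frame)
            p_hi = np.mean([mm.compute_track_metrics(t, frame).persistence for t in hi])
            p_lo = np.mean([mm.compute_track_metrics(t, frame).persistence for t in lo])
            assert p_hi > p_lo

    def test_paper_scale_arithmetic(self):
        """1 um/min at 6-min steps for 60 steps: 6 h elapsed, 360 um path."""
        params = SyntheticParams(seed=0, track_speed_um_min=1.0, track_dt_min=6.0,
                                 track_n_steps=60)
        tracks, _ = simulate_tracks(params, 1, FRAME)
        m = mm.compute_track_metrics(tracks[0], FRAME)
        assert tracks[0].times_min[-1] - tracks[0].times_min[0] == pytest.approx(360.0)
        assert m.path_length_um == pytest.approx(360.0)

    def test_too_few_steps_raises(self):
        from micromot.errors import GeometryError

        with pytest.raises(GeometryError):
            simulate_tracks(SyntheticParams(seed=0, track_n_steps=1), 1, FRAME)


def test_table_roundtrip():
    params = SyntheticParams(seed=4)
    tracks, _ = simulate_tracks(params, 3, FRAME)
    for t in tracks:
        t.condition = "ctrl"
    table = mm.tracks_to_table(tracks)
    back = mm.tracks_from_table(table)
    assert len(back) == 3
    for a, b in zip(tracks, back):
        np.testing.assert_allclose(a.positions_um, b.positions_um)
        assert b.condition == "ctrl"


def test_table_missing_columns_raise():
    with pytest.raises(TrackError):
        mm.tracks_from_table(pd.DataFrame({"cell_id": ["a"], "t_min": [0.0]}))
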