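"""Track tables, axis projection, jump filter, running-window smoothing."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from motortrace import (
    ProjectedTrack,
    Trajectory,
    filter_jumps,
    project_onto_axis,
    read_tracks,
    running_window_average,
    write_tracks,
)


def make_traj(x, y=None, dt=0.1, tid="t0"):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return Trajectory(tid, np.arange(len(x)) * dt, x, y, dt)


def make_projected(s, dt=0.1, tid="p0"):
    s = np.asarray(s, dtype=float)
    return ProjectedTrack(tid, np.arange(len(s)) * dt, s, np.zeros_like(s))


class TestTrackTableIO:
    def test_round_trip(self):
        trajs = [
            make_traj([0, 10, 20, 35], [1, 2, 1, 0], tid="a"),
            make_traj([5, 5, 6], [0, 0.5, 1], tid="b"),
        ]
        buf = io.StringIO()
        write_tracks(trajs, buf)
        buf.seek(0)
        back = read_tracks(buf)
        assert len(back) == 2
        for orig, rt in zip(trajs, back):
            np.testing.assert_allclose(rt.x, orig.x)
            np.testing.assert_allclose(rt.y, orig.y)
            np.testing.assert_allclose(rt.times, orig.times)

    def test_duplicated_frame_names_track_and_frame(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "track_id,frame,t_s,x_nm,y_nm,label\n"
            "a,0,0.0,0,0,x\na,1,0.1,1,0,x\na,1,0.1,2,0,x\n"
        )
        with pytest.raises(ValueError, match="track a.*frame 1"):
            read_tracks(p)

    def test_frame_gap_rejected(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text(
            "track_id,frame,t_s,x_nm,y_nm,label\n"
            "a,0,0.0,0,0,x\na,2,0.2,1,0,x\na,3,0.3,2,0,x\n"
        )
        with pytest.raises(ValueError, match="gap"):
            read_tracks(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("track_id,frame,t_s\na,0,0.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_tracks(p)


class TestProjection:
    def test_collinear_diagonal_track(self):
        """100 nm in x and y → net on-axis displacement 100√2, no residual."""
        x = np.linspace(0, 100, 11)
        proj = project_onto_axis(make_traj(x, x))
        assert proj.net_displacement == pytest.approx(100 * np.sqrt(2), rel=1e-9)
        np.testing.assert_allclose(proj.s_perp, 0.0, atol=1e-9)

    def test_perpendicular_scatter_about_horizontal_axis(self, rng):
        x = np.linspace(0, 1000, 200)
        y = rng.normal(0, 20, 200)
        proj = project_onto_axis(make_traj(x, y))
        assert proj.net_displacement == pytest.approx(1000, rel=0.01)
        assert proj.s_perp.std() == pytest.approx(y.std(), rel=0.05)

    def test_squared_deviation_preserved(self, rng):
        x = np.cumsum(rng.normal(10, 30, 100))
        y = rng.normal(0, 25, 100)
        proj = project_onto_axis(make_traj(x, y))
        orig = np.var(x) + np.var(y)
        assert np.var(proj.s_axis) + np.var(proj.s_perp) == pytest.approx(
            orig, rel=1e-6
        )

    @given(st.floats(0.0, 2 * np.pi))
    def test_rotation_invariance(self, angle):
        rng = np.random.default_rng(99)
        x = np.cumsum(rng.normal(20, 10, 50))
        y = rng.normal(0, 15, 50)
        base = project_onto_axis(make_traj(x, y))
        c, s = np.cos(angle), np.sin(angle)
        rot = project_onto_axis(make_traj(c * x - s * y, s * x + c * y))
        np.testing.assert_allclose(rot.s_axis, base.s_axis, atol=1e-6)
        np.testing.assert_allclose(np.abs(rot.s_perp), np.abs(base.s_perp), atol=1e-6)

    def test_degenerate_track_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            project_onto_axis(make_traj([5.0, 5.0, 5.0]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            project_onto_axis(make_traj([0.0, 1.0]))


class TestJumpFilter:
    def test_constant_velocity_accepted(self):
        res = filter_jumps(make_projected(np.arange(20) * 50.0))
        assert res.accepted

    def test_single_jump_reported_with_frame(self):
        s = np.arange(10) * 10.0
        s[7:] += 150.0
        res = filter_jumps(make_projected(s))
        assert not res.accepted
        assert res.offending_frames == (7,)

    def test_infinite_threshold_accepts_anything(self):
        s = np.array([0.0, 1e6, -1e6, 0.0])
        assert filter_jumps(make_projected(s), max_jump=np.inf).accepted

    @given(st.floats(10.0, 500.0), st.floats(0.0, 400.0))
    def test_monotone_in_threshold(self, lo, extra):
        rng = np.random.default_rng(7)
        s = np.cumsum(rng.normal(30, 40, 40))
        a = filter_jumps(make_projected(s), max_jump=lo)
        b = filter_jumps(make_projected(s), max_jump=lo + extra)
        assert b.accepted or not a.accepted


class TestRunningWindow:
    def test_window_one_is_identity(self):
        track = make_projected([0.0, 30.0, 0.0])
        out = running_window_average(track, 1)
        np.testing.assert_array_equal(out.s_axis, track.s_axis)

    def test_window_three_arithmetic(self):
        out = running_window_average(make_projected([0.0, 30.0, 0.0]), 3)
        assert out.s_axis[1] == pytest.approx(10.0)
        assert out.window == 3

    def test_even_or_oversized_window_rejected(self):
        track = make_projected(np.arange(5.0))
        with pytest.raises(ValueError):
            running_window_average(track, 2)
        with pytest.raises(ValueError):
            running_window_average(track, 7)

    def test_noise_reduction_scales_with_sqrt_window(self, rng):
        sigma, w = 30.0, 5
        track = make_projected(rng.normal(0, sigma, 20_000))
        out = running_window_average(track, w)
        interior = out.s_axis[w:-w]
        assert interior.std() == pytest.approx(sigma / np.sqrt(w), rel=0.05)

    @given(st.floats(-1e4, 1e4))
    def test_commutes_with_constant_offset(self, offset):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 50, 30)
        a = running_window_average(make_projected(s + offset), 5).s_axis
        b = running_window_average(make_projected(s), 5).s_axis + offset
        np.testing.assert_allclose(a, b, atol=1e-6)
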