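"""Track tables, microtubule-axis projection, jump filtering, smoothing.

Tracks arrive as (track_id, frame, t, x, y) tables from upstream
detection/linking software.  Each 2D track is projected onto the long axis
of its microtubule — estimated by a total-least-squares line fit — giving a
1D on-axis coordinate (plus-end positive by the net-displacement
convention) and a perpendicular residual.  Quality control excludes tracks
with frame-to-frame jumps above a threshold, and a centered running-window
mean suppresses localization noise before residence-time binning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "ProjectedTrack",
    "JumpFilterResult",
    "read_tracks",
    "write_tracks",
    "project_onto_axis",
    "filter_jumps",
    "running_window_average",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_nm", "y_nm", "label"]


@dataclass
class ProjectedTrack:
    """1D decomposition of a 2D track about its fitted microtubule axis."""

    track_id: str
    times: np.ndarray
    s_axis: np.ndarray   # nm along the MT axis, net displacement positive
    s_perp: np.ndarray   # nm, signed orthogonal residual
    window: int = 1      # frames of running average applied (1 = none)
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.s_axis = np.asarray(self.s_axis, dtype=float)
        self.s_perp = np.asarray(self.s_perp, dtype=float)
        if not len(self.times) == len(self.s_axis) == len(self.s_perp):
            raise ValueError("times, s_axis, s_perp must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def net_displacement(self) -> float:
        return float(self.s_axis[-1] - self.s_axis[0])

    @property
    def span(self) -> float:
        """Extent of the on-axis coordinate, nm."""
        return float(self.s_axis.max() - self.s_axis.min())


@dataclass(frozen=True)
class JumpFilterResult:
    accepted: bool
    offending_frames: tuple[int, ...]
    max_observed_jump: float


def write_tracks(trajectories: list[Trajectory], path) -> None:
    """Write trajectories as a delimited track table (one row per frame)."""
    rows = []
    for traj in trajectories:
        for i in range(traj.n_frames):
            rows.append(
                (traj.track_id, i, traj.times[i], traj.x[i], traj.y[i], traj.label)
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)


def read_tracks(path) -> list[Trajectory]:
    """Read a track table into one Trajectory per track_id.

    Rows are sorted by frame within each track; duplicated or gapped frames
    and mixed frame intervals are rejected with the offending track named.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if "label" not in df.columns:
        df["label"] = ""
    out: list[Trajectory] = []
    for tid, group in df.groupby("track_id", sort=False):
        g = group.sort_values("frame")
        frames = g["frame"].to_numpy()
        d = np.diff(frames)
        if np.any(d == 0):
            bad = int(frames[np.flatnonzero(d == 0)[0]])
            raise ValueError(f"track {tid}: duplicated frame {bad}")
        if np.any(d != 1):
            bad = int(frames[np.flatnonzero(d != 1)[0]])
            raise ValueError(f"track {tid}: frame gap after frame {bad}")
        times = g["t_s"].to_numpy(dtype=float)
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError(f"track {tid}: mixed frame intervals")
        out.append(
            Trajectory(
                track_id=str(tid),
                times=times,
                x=g["x_nm"].to_numpy(dtype=float),
                y=g["y_nm"].to_numpy(dtype=float),
                frame_interval=float(dts[0]),
                label=str(g["label"].iloc[0]),
            )
        )
    return out


def project_onto_axis(traj: Trajectory) -> ProjectedTrack:
    """Split a 2D track into on-axis and perpendicular 1D components.

    The microtubule axis is the total-least-squares line through (x, y)
    (principal eigenvector of the positional covariance), which is
    symmetric in x and y.  The on-axis coordinate is oriented so the
    track's net displacement is positive; the sign convention does not
    claim to match MT polarity.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames to fit an axis")
    xy = np.column_stack([traj.x, traj.y])
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    if np.allclose(cov, 0):
        raise ValueError("degenerate track: all points identical")
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    perp = np.array([-axis[1], axis[0]])
    s_axis = centered @ axis
    s_perp = centered @ perp
    if s_axis[-1] - s_axis[0] < 0:
        s_axis = -s_axis
        s_perp = -s_perp
    return ProjectedTrack(
        track_id=traj.track_id,
        times=traj.times.copy(),
        s_axis=s_axis,
        s_perp=s_perp,
        window=1,
        source=traj.label,
    )


def filter_jumps(track: ProjectedTrack, max_jump: float = 100.0) -> JumpFilterResult:
    """Flag tracks with frame-to-frame displacements above ``max_jump`` nm.

    The displacement is the full 2D magnitude sqrt(ds_axis² + ds_perp²).
    Automates the manual review step that excluded tracks with jumps
    greater than 100 nm.
    """
    steps = np.hypot(np.diff(track.s_axis), np.diff(track.s_perp))
    bad = np.flatnonzero(steps > max_jump) + 1  # frame index of the landing point
    return JumpFilterResult(
        accepted=bad.size == 0,
        offending_frames=tuple(int(b) for b in bad),
        max_observed_jump=float(steps.max()) if steps.size else 0.0,
    )


def _centered_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with shrunken windows at the edges."""
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def running_window_average(track: ProjectedTrack, window: int) -> ProjectedTrack:
    """Smooth a projected track with a centered odd-width moving mean.

    Edge frames use shrunken windows so trace length (and hence total
    residence time) is conserved.  window = 1 returns the track unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > track.n_frames:
        raise ValueError("window exceeds trace length")
    if window == 1:
        return replace(track)
    return ProjectedTrack(
        track_id=track.track_id,
        times=track.times.copy(),
        s_axis=_centered_mean(track.s_axis, window),
        s_perp=_centered_mean(track.s_perp, window),
        window=window,
        source=track.source,
    )


def write_projected(tracks: list[ProjectedTrack], path) -> None:
    """Write projected tracks as `track_id,frame,t_s,s_axis_nm,s_perp_nm`."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            rows.append((tr.track_id, i, tr.times[i], tr.s_axis[i], tr.s_perp[i]))
    pd.DataFrame(
        rows, columns=["track_id", "frame", "t_s", "s_axis_nm", "s_perp_nm"]
    ).to_csv(path, index=False)
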