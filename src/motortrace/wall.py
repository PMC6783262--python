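"""Wall-encounter classification and pause-duration fitting for bead cargos.

When a multi-motor bead carried below a suspended microtubule reaches the
ridge wall it must rotate to the top of the MT before continuing.  The
rotation shows up as a light-to-dark transition in the bead's brightfield
intensity at the wall.  Events are classified as pass (immediate
rotation), pause_pass (dwell longer than a threshold before rotating),
stuck (no rotation, position persists) or detach (trace ends at the
wall).  Pause-pass dwell times are fit with a single exponential on the
empirical 1-CDF, whose decay time is the mean wall pause.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expfit import ExpFit, empirical_survival, fit_exponential_survival
from .simulate import WallEncounterEvent

__all__ = [
    "OutcomeTally",
    "WallPauseModel",
    "WallPauseResults",
    "classify_event",
    "tally_outcomes",
    "fit_pause_times",
]

OUTCOMES = ("pass", "pause_pass", "detach", "stuck")
DEFAULT_PAUSE_THRESHOLD_S = 1.0
DEFAULT_TRANSITION_DROP = 0.3
RESUME_ADVANCE_NM = 100.0


def classify_event(
    event: WallEncounterEvent,
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD_S,
    transition_drop: float = DEFAULT_TRANSITION_DROP,
    resume_advance: float = RESUME_ADVANCE_NM,
) -> WallEncounterEvent:
    """Classify one wall encounter; fills ``outcome`` and ``pause_duration``.

    A rotation is a relative intensity drop ≥ ``transition_drop`` between
    the pre-wall and post-wall medians.  Resumed forward motion means the
    position advances ≥ ``resume_advance`` nm beyond the wall plateau
    within the trace; the dwell is the time from wall arrival to the first
    frame past the plateau.  No rotation and no resumption is stuck when
    the trace outlives the arrival substantially, detach when it ends at
    the wall; a trace too short to tell stays unclassified.
    """
    t, pos, inten = event.times, event.position, event.intensity
    at_wall = t >= event.wall_time
    pre = inten[~at_wall]
    post = inten[at_wall]
    if pre.size == 0 or post.size == 0:
        event.outcome = None
        return event
    wall_pos = pos[at_wall][0]
    advanced = at_wall & (pos > wall_pos + resume_advance)
    resumed = bool(np.any(advanced))
    baseline = float(np.median(pre))
    drop = (baseline - float(np.median(post))) / baseline if baseline > 0 else 0.0
    rotated = drop >= transition_drop
    if resumed:
        # dwell ends at the first frame that has left the wall plateau
        departed = at_wall & (pos > wall_pos + 1e-6)
        t_depart = t[departed][0] if np.any(departed) else t[advanced][0]
        dwell = float(max(t_depart - event.wall_time - (t[1] - t[0]), 0.0))
        event.pause_duration = dwell
        event.outcome = "pause_pass" if dwell > pause_threshold else "pass"
        return event
    # no resumption: distinguish stuck from detach by how long the trace
    # persists at the wall
    time_at_wall = t[-1] - event.wall_time
    if time_at_wall <= 3 * (t[1] - t[0]):
        event.outcome = "detach"
    elif not rotated:
        event.outcome = "stuck"
    else:
        event.outcome = None  # rotated but never resumed and never ended
    event.pause_duration = 0.0
    return event


@dataclass(frozen=True)
class OutcomeTally:
    counts: dict
    fractions: dict
    binomial_sd: dict
    n_events: int

    def summary(self) -> str:
        lines = ["Wall-encounter outcomes", "=" * 40]
        for k in OUTCOMES:
            lines.append(
                f"{k:<12}{self.counts[k]:>6d}  "
                f"{100 * self.fractions[k]:6.1f} ± {100 * self.binomial_sd[k]:.1f} %"
            )
        lines.append(f"{'total':<12}{self.n_events:>6d}")
        lines.append("=" * 40)
        return "\n".join(lines)


def tally_outcomes(events: list[WallEncounterEvent]) -> OutcomeTally:
    """Counts and binomial fractions per outcome class."""
    if not events:
        raise ValueError("empty event set")
    unclassified = [e.event_id for e in events if e.outcome not in OUTCOMES]
    if unclassified:
        raise ValueError(f"unclassified events: {unclassified[:5]}")
    n = len(events)
    counts = {k: sum(e.outcome == k for e in events) for k in OUTCOMES}
    fractions = {k: counts[k] / n for k in OUTCOMES}
    sds = {k: float(np.sqrt(fractions[k] * (1 - fractions[k]) / n)) for k in OUTCOMES}
    return OutcomeTally(counts=counts, fractions=fractions, binomial_sd=sds, n_events=n)


class WallPauseModel:
    """Exponential model of wall-pause durations (s)."""

    MIN_N = 5

    def __init__(self, durations_s: np.ndarray):
        d = np.asarray(durations_s, dtype=float)
        if d.size < self.MIN_N:
            raise ValueError(f"need at least {self.MIN_N} pause durations")
        if np.any(d <= 0):
            raise ValueError("pause durations must be positive")
        self.durations = d

    @classmethod
    def from_events(cls, events: list[WallEncounterEvent]) -> "WallPauseModel":
        d = [e.pause_duration for e in events if e.outcome == "pause_pass"]
        return cls(np.asarray(d))

    def fit(self) -> "WallPauseResults":
        t, y = empirical_survival(self.durations)
        fit = fit_exponential_survival(t, y, tau0=float(self.durations.mean()))
        return WallPauseResults(model=self, expfit=fit)


@dataclass
class WallPauseResults:
    model: WallPauseModel
    expfit: ExpFit

    @property
    def mean_pause(self) -> float:
        """Decay time of the 1-CDF fit, s."""
        return self.expfit.tau

    @property
    def stderr(self) -> float:
        return self.expfit.tau_stderr

    def summary(self) -> str:
        return "\n".join(
            [
                "Wall-pause exponential fit (1-CDF)",
                "=" * 40,
                f"{'n pauses':<24}{self.model.durations.size:>16d}",
                f"{'mean pause (s)':<24}{self.mean_pause:>10.2f} ± {self.stderr:.2f}",
                "=" * 40,
            ]
        )


def fit_pause_times(durations_s: np.ndarray) -> tuple[float, float]:
    """(mean pause time, fit stderr) from the 1-CDF single-exponential fit."""
    res = WallPauseModel(durations_s).fit()
    return res.mean_pause, res.stderr
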