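"""Synthetic stepping trajectories and related ensembles.

The simulator emulates the data-generating process the downstream analysis
assumes: a motor takes 8 nm unidirectional steps along the microtubule axis
with exponentially distributed dwell times, drawn from a fast (processive)
state or, with a per-step probability set by the target pause density, from
a slow (paused) state.  The continuous-time path is resampled to the camera
frame rate by sample-and-hold and Gaussian localization noise is added to
every coordinate.  Ground truth (step times, pause flags) is kept alongside
each trace so estimator recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "StepperConfig",
    "Trajectory",
    "StepperTruth",
    "WallEncounterEvent",
    "simulate_stepper_trace",
    "simulate_ensemble",
    "resample_to_frames",
    "add_localization_noise",
    "simulate_run_length_ensemble",
    "simulate_wall_encounters",
]

STEP_SIZE_NM = 8.0
NM_PER_UM = 1000.0


@dataclass(frozen=True)
class StepperConfig:
    """Parameters of the two-state stepping simulation.

    Attributes
    ----------
    step_size : float
        Forward step size in nm (8 nm, one tubulin dimer).
    dwell_fast : float
        Mean dwell of the processive state, s.
    dwell_pause : float
        Mean dwell of the paused state, s.
    pause_density_true : float
        Ground-truth pauses per µm of travel; sets the per-step pause
        probability ``q = pause_density_true * step_size / 1000``.
    frame_rate : float
        Camera frame rate, Hz.
    loc_error_sigma : float
        SD of additive Gaussian localization noise, nm.
    duration : float
        Trace duration, s.
    n_traces : int
        Number of traces in an ensemble.
    seed : int
        Base seed for ensemble generation.
    """

    step_size: float = STEP_SIZE_NM
    dwell_fast: float = 0.015
    dwell_pause: float = 0.59
    pause_density_true: float = 0.0
    frame_rate: float = 10.0
    loc_error_sigma: float = 30.0
    duration: float = 5.0
    n_traces: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_size", "dwell_fast", "dwell_pause", "frame_rate", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pause_density_true < 0:
            raise ValueError("pause_density_true must be >= 0")
        if self.loc_error_sigma < 0:
            raise ValueError("loc_error_sigma must be >= 0")
        if self.frame_rate * self.duration < 10:
            raise ValueError("duration too short: need at least 10 frames")
        if self.pause_probability > 1:
            raise ValueError(
                "pause_density_true too high for the per-step mixture model "
                f"(q = {self.pause_probability:.3f} > 1)"
            )

    @property
    def pause_probability(self) -> float:
        """Per-step probability that the dwell is drawn from the paused state."""
        return self.pause_density_true * self.step_size / NM_PER_UM


@dataclass
class Trajectory:
    """Camera-sampled 2D positions of one probe.

    times are strictly increasing with constant spacing ``frame_interval``;
    x/y are in nm.
    """

    track_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("times, x and y must have equal length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, self.frame_interval, rtol=1e-9, atol=1e-12):
            raise ValueError("frame spacing must equal frame_interval")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class StepperTruth:
    """Ground truth of one simulated trace: per-step times and pause flags."""

    step_times: np.ndarray
    is_pause: np.ndarray  # dwell preceding each step drawn from the paused state

    @property
    def n_steps(self) -> int:
        return len(self.step_times)

    @property
    def n_pauses(self) -> int:
        return int(np.sum(self.is_pause))


@dataclass
class WallEncounterEvent:
    """Bead intensity/position trace around an arrival at the ridge wall."""

    event_id: str
    times: np.ndarray
    intensity: np.ndarray
    position: np.ndarray
    wall_time: float
    outcome: str | None = None
    pause_duration: float = 0.0
    true_outcome: str | None = None
    true_pause: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if not (self.times[0] <= self.wall_time <= self.times[-1]):
            raise ValueError("wall_time must lie within the trace")


def _simulate_steps(config: StepperConfig, rng: np.random.Generator) -> StepperTruth:
    """Draw the continuous-time step sequence over [0, duration]."""
    # Expected steps + slack; extend in the rare case the budget runs out.
    q = config.pause_probability
    mean_dwell = (1 - q) * config.dwell_fast + q * config.dwell_pause
    step_times: list[float] = []
    flags: list[bool] = []
    t = 0.0
    n_guess = max(16, int(1.5 * config.duration / mean_dwell) + 20)
    while True:
        pauses = rng.random(n_guess) < q
        dwells = np.where(
            pauses,
            rng.exponential(config.dwell_pause, n_guess),
            rng.exponential(config.dwell_fast, n_guess),
        )
        ts = t + np.cumsum(dwells)
        inside = ts <= config.duration
        step_times.extend(ts[inside].tolist())
        flags.extend(pauses[inside].tolist())
        if not inside.all():
            break
        t = float(ts[-1])
        n_guess = max(16, n_guess // 4)
    return StepperTruth(
        step_times=np.asarray(step_times), is_pause=np.asarray(flags, dtype=bool)
    )


def resample_to_frames(
    event_times: np.ndarray,
    positions: np.ndarray,
    frame_rate: float,
    duration: float | None = None,
    track_id: str = "sim",
    label: str = "",
) -> Trajectory:
    """Resample an instantaneous stepping path to camera frames.

    Sample-and-hold: the position at frame time ``t`` is the position
    immediately after the last step at or before ``t`` (0 before the first
    step).  Output positions are therefore non-decreasing for a forward
    stepper.
    """
    event_times = np.asarray(event_times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if len(event_times) != len(positions):
        raise ValueError("event_times and positions must have equal length")
    if duration is None:
        if len(event_times) == 0:
            raise ValueError("empty path and no duration given")
        duration = float(event_times[-1])
    dt = 1.0 / frame_rate
    n_frames = int(np.floor(duration * frame_rate)) + 1
    if n_frames < 2:
        raise ValueError("fewer than 2 frames in the sampling window")
    frame_times = np.arange(n_frames) * dt
    if len(event_times) == 0:
        held = np.zeros(n_frames)
    else:
        idx = np.searchsorted(event_times, frame_times, side="right")
        held = np.concatenate(([0.0], positions))[idx]
    return Trajectory(
        track_id=track_id,
        times=frame_times,
        x=held,
        y=np.zeros(n_frames),
        frame_interval=dt,
        label=label,
    )


def add_localization_noise(
    traj: Trajectory, sigma: float, seed: int | np.random.Generator
) -> Trajectory:
    """Add i.i.d. zero-mean Gaussian noise of SD ``sigma`` (nm) to x and y."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return traj
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Trajectory(
        track_id=traj.track_id,
        times=traj.times.copy(),
        x=traj.x + rng.normal(0.0, sigma, traj.n_frames),
        y=traj.y + rng.normal(0.0, sigma, traj.n_frames),
        frame_interval=traj.frame_interval,
        label=traj.label,
    )


def simulate_stepper_trace(
    config: StepperConfig, seed: int | np.random.Generator, track_id: str = "sim-0"
) -> tuple[Trajectory, StepperTruth]:
    """Simulate one camera-sampled noisy stepping trace plus its ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = _simulate_steps(config, rng)
    positions = config.step_size * np.arange(1, truth.n_steps + 1)
    traj = resample_to_frames(
        truth.step_times,
        positions,
        config.frame_rate,
        duration=config.duration,
        track_id=track_id,
        label="sim",
    )
    traj = add_localization_noise(traj, config.loc_error_sigma, rng)
    return traj, truth


def simulate_ensemble(
    config: StepperConfig, seed: int | None = None
) -> tuple[list[Trajectory], list[StepperTruth]]:
    """Simulate ``config.n_traces`` independent traces from one seeded stream."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trajs, truths = [], []
    for i in range(config.n_traces):
        traj, truth = simulate_stepper_trace(config, rng, track_id=f"sim-{i}")
        trajs.append(traj)
        truths.append(truth)
    return trajs, truths


def truth_sidecar(config: StepperConfig, truths: list[StepperTruth]) -> str:
    """JSON record of the generating config and per-trace ground truth."""
    payload = {
        "config": asdict(config),
        "traces": [
            {"n_steps": t.n_steps, "n_pauses": t.n_pauses} for t in truths
        ],
    }
    return json.dumps(payload, indent=1)


def simulate_run_length_ensemble(
    decay_constant_um: float,
    n: int,
    immobile_fraction: float = 0.0,
    velocity_mean: float = 533.0,
    velocity_cv: float = 0.1,
    seed: int = 0,
    frame_rate: float = 10.0,
    loc_error_sigma: float = 20.0,
) -> list[Trajectory]:
    """Ensemble of constant-velocity runs with exponential total run length.

    Each mobile trace draws an exponential run length (mean
    ``decay_constant_um``, µm) and a per-trace velocity (Gaussian,
    truncated at zero); immobile traces sit still apart from localization
    noise.  Both kinds carry noise in x and y.
    """
    if decay_constant_um <= 0:
        raise ValueError("decay_constant_um must be positive")
    if not 0 <= immobile_fraction <= 1:
        raise ValueError("immobile_fraction must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    out: list[Trajectory] = []
    for i in range(n):
        immobile = rng.random() < immobile_fraction
        if immobile:
            n_frames = 50
            x = np.zeros(n_frames)
        else:
            run_nm = rng.exponential(decay_constant_um) * NM_PER_UM
            v = -1.0
            while v <= 0:
                v = rng.normal(velocity_mean, velocity_cv * velocity_mean)
            t_end = run_nm / v
            n_frames = max(3, int(np.floor(t_end * frame_rate)) + 1)
            x = np.minimum(v * np.arange(n_frames) * dt, run_nm)
        times = np.arange(n_frames) * dt
        traj = Trajectory(
            track_id=f"run-{i}",
            times=times,
            x=x,
            y=np.zeros(n_frames),
            frame_interval=dt,
            label="immobile" if immobile else "mobile",
        )
        out.append(add_localization_noise(traj, loc_error_sigma, rng))
    return out


def net_run_length_um(traj: Trajectory) -> float:
    """Net x displacement of a trace in µm (run length of a 1D run)."""
    return float(traj.x[-1] - traj.x[0]) / NM_PER_UM


def simulate_wall_encounters(
    n: int,
    outcome_probs: tuple[float, float, float] = (0.5, 0.3, 0.2),
    pause_mean: float = 3.8,
    seed: int = 0,
    frame_rate: float = 10.0,
    velocity: float = 500.0,
    wall_position: float = 2000.0,
    intensity_drop: float = 0.5,
    intensity_noise: float = 0.03,
    pause_threshold: float = 1.0,
) -> list[WallEncounterEvent]:
    """Generate bead wall-encounter events with known outcomes.

    ``outcome_probs`` are (pass, pause_pass, detach_or_stuck); they must sum
    to 1.  Pass events dwell briefly (uniform below ``pause_threshold``)
    before the light-to-dark rotation signature; pause-pass events add an
    exponential dwell of mean ``pause_mean``; failures either truncate at
    the wall (detach) or stall indefinitely (stuck, equal split).
    """
    probs = np.asarray(outcome_probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("outcome_probs must be 3 proportions summing to 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    events: list[WallEncounterEvent] = []
    t_wall = wall_position / velocity
    for i in range(n):
        kind = rng.choice(3, p=probs)
        if kind == 0:
            dwell = float(rng.uniform(0.0, 0.5 * pause_threshold))
            outcome = "pass"
        elif kind == 1:
            dwell = float(rng.exponential(pause_mean))
            outcome = "pause_pass"
        else:
            dwell = 0.0
            outcome = "detach" if rng.random() < 0.5 else "stuck"
        # quantize arrival to the frame grid so dwell is measured exactly
        wall_time = np.ceil(t_wall / dt) * dt
        post_run = 600.0  # nm of forward travel after passing
        if outcome in ("pass", "pause_pass"):
            total_t = wall_time + dwell + post_run / velocity + dt
        elif outcome == "stuck":
            total_t = wall_time + max(6.0, 3 * pause_mean)
        else:  # detach: trace ends shortly after arrival
            total_t = wall_time + 2 * dt
        n_frames = max(4, int(np.floor(total_t / dt)) + 1)
        times = np.arange(n_frames) * dt
        pos = np.minimum(velocity * times, wall_position)
        intensity = np.ones(n_frames)
        if outcome in ("pass", "pause_pass"):
            resume = wall_time + dwell
            moving = times > resume
            pos[moving] = wall_position + velocity * (times[moving] - resume)
            # bead rotates to the dark side of the MT at the wall
            intensity[times >= wall_time] = 1.0 - intensity_drop
        elif outcome == "stuck":
            intensity[times >= wall_time] = 1.0  # never rotates
        intensity += rng.normal(0.0, intensity_noise, n_frames)
        events.append(
            WallEncounterEvent(
                event_id=f"ev-{i}",
                times=times,
                intensity=intensity,
                position=pos,
                wall_time=float(wall_time),
                true_outcome=outcome,
                true_pause=dwell if outcome == "pause_pass" else 0.0,
            )
        )
    return events
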