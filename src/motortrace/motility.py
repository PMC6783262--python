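"""Motility statistics: mobile fraction, velocity, run length, comparisons.

Run lengths are exponentially distributed; the decay constant λ of a
single-exponential fit to the empirical 1-CDF is the primary run-length
value, and the half-life ln(2)·λ is reported alongside it (both
conventions appear in the field).  Velocity is the endpoint convention —
net on-axis displacement over trace duration, pauses included — matching
kymograph start/end measurement.  Mobile fraction is the number of tracks
with net displacement above a threshold over all tracks observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expfit import ExpFit, empirical_survival, fit_exponential_survival
from .tracks import ProjectedTrack

__all__ = [
    "MotilitySummary",
    "RunLengthModel",
    "RunLengthResults",
    "compute_mobile_fraction",
    "compute_velocity",
    "fit_run_length",
    "summarize_condition",
    "normalize_to_control",
    "compare_conditions",
]

DEFAULT_MIN_DISPLACEMENT_NM = 250.0
LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class MotilitySummary:
    """Per-condition motility statistics."""

    condition: str
    n_total: int
    n_mobile: int
    mobile_fraction: float
    velocity_mean: float      # nm/s
    velocity_sd: float        # nm/s
    run_length_decay: float   # µm, decay constant λ
    run_length_halflife: float  # µm, ln(2)·λ
    fit_error: float          # µm, stderr of λ

    def normalized_to(self, control: "MotilitySummary") -> dict:
        return normalize_to_control(self, control)


def compute_mobile_fraction(
    tracks: list[ProjectedTrack],
    min_displacement: float = DEFAULT_MIN_DISPLACEMENT_NM,
) -> tuple[int, int, float]:
    """(n_mobile, n_total, fraction) with net on-axis displacement ≥ threshold."""
    if not tracks:
        raise ValueError("empty track set")
    n_total = len(tracks)
    n_mobile = sum(t.net_displacement >= min_displacement for t in tracks)
    return n_mobile, n_total, n_mobile / n_total


def compute_velocity(track: ProjectedTrack) -> float:
    """Endpoint velocity in nm/s: net displacement / duration, pauses included."""
    duration = track.times[-1] - track.times[0]
    if duration <= 0:
        raise ValueError("zero-duration track")
    return track.net_displacement / duration


class RunLengthModel:
    """Single-exponential model of a run-length sample (µm).

    fit() performs the unweighted least-squares fit of A·exp(−L/λ) to the
    empirical 1-CDF and returns a :class:`RunLengthResults`.
    """

    MIN_N = 30

    def __init__(self, run_lengths_um: np.ndarray):
        rl = np.asarray(run_lengths_um, dtype=float)
        if rl.size < self.MIN_N:
            raise ValueError(f"need at least {self.MIN_N} run lengths, got {rl.size}")
        if np.any(rl <= 0):
            raise ValueError("run lengths must be positive")
        self.run_lengths = rl

    def fit(self) -> "RunLengthResults":
        t, y = empirical_survival(self.run_lengths)
        fit = fit_exponential_survival(t, y, tau0=float(self.run_lengths.mean()))
        return RunLengthResults(model=self, expfit=fit)


@dataclass
class RunLengthResults:
    model: RunLengthModel
    expfit: ExpFit

    @property
    def decay_constant(self) -> float:
        """λ in µm."""
        return self.expfit.tau

    @property
    def half_life(self) -> float:
        """ln(2)·λ in µm."""
        return LN2 * self.expfit.tau

    @property
    def stderr(self) -> float:
        return self.expfit.tau_stderr

    @property
    def mle_mean(self) -> float:
        """Closed-form exponential MLE (the sample mean), for cross-checks."""
        return float(self.model.run_lengths.mean())

    def summary(self) -> str:
        n = self.model.run_lengths.size
        return "\n".join(
            [
                "Run-length exponential fit (1-CDF)",
                "=" * 42,
                f"{'n runs':<26}{n:>16d}",
                f"{'decay constant λ (µm)':<26}{self.decay_constant:>10.3f} ± {self.stderr:.3f}",
                f"{'half-life ln2·λ (µm)':<26}{self.half_life:>16.3f}",
                f"{'sample mean (µm)':<26}{self.mle_mean:>16.3f}",
                "=" * 42,
            ]
        )


def fit_run_length(run_lengths_um: np.ndarray) -> tuple[float, float, float]:
    """(decay constant λ, half-life, λ stderr) in µm."""
    res = RunLengthModel(run_lengths_um).fit()
    return res.decay_constant, res.half_life, res.stderr


def summarize_condition(
    tracks: list[ProjectedTrack],
    condition: str = "",
    min_displacement: float = DEFAULT_MIN_DISPLACEMENT_NM,
) -> MotilitySummary:
    """Mobile fraction, velocity and run-length fit for one condition."""
    n_mobile, n_total, frac = compute_mobile_fraction(tracks, min_displacement)
    mobile = [t for t in tracks if t.net_displacement >= min_displacement]
    velocities = np.array([compute_velocity(t) for t in mobile]) if mobile else np.array([])
    run_lengths_um = np.array([t.net_displacement / 1000.0 for t in mobile])
    if run_lengths_um.size >= RunLengthModel.MIN_N:
        decay, half, err = fit_run_length(run_lengths_um)
    else:
        decay = half = err = float("nan")
    return MotilitySummary(
        condition=condition,
        n_total=n_total,
        n_mobile=n_mobile,
        mobile_fraction=frac,
        velocity_mean=float(velocities.mean()) if velocities.size else float("nan"),
        velocity_sd=float(velocities.std(ddof=1)) if velocities.size > 1 else float("nan"),
        run_length_decay=decay,
        run_length_halflife=half,
        fit_error=err,
    )


_NORMALIZED_FIELDS = ("mobile_fraction", "velocity_mean", "run_length_decay",
                      "run_length_halflife")


def normalize_to_control(summary: MotilitySummary, control: MotilitySummary) -> dict:
    """Each metric divided by the matching control value (control → 1.0)."""
    out = {}
    for name in _NORMALIZED_FIELDS:
        c = getattr(control, name)
        if c == 0:
            raise ZeroDivisionError(f"control metric {name} is zero")
        out[name] = getattr(summary, name) / c
    return out


def compare_conditions(a, b, test: str = "t_test") -> tuple[float, float]:
    """Two-sample comparison: returns (statistic, p-value).

    t_test
        Welch two-tailed t-test on two samples of measurements.
    z_proportions
        Two-proportion z-test; a and b are (successes, total) pairs.
    f_test_expfits
        Extra-sum-of-squares F-test asking whether two pause-time (or
        run-length) samples need separate exponential decay constants, or
        a shared one suffices.  a and b are the raw positive samples.
    """
    if test == "t_test":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs at least 2 observations per sample")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "z_proportions":
        from statsmodels.stats.proportion import proportions_ztest

        (ka, na), (kb, nb) = a, b
        stat, p = proportions_ztest([ka, kb], [na, nb])
        return float(stat), float(p)
    if test == "f_test_expfits":
        return _f_test_exponential(np.asarray(a, float), np.asarray(b, float))
    raise ValueError(f"unknown test {test!r}")


def _f_test_exponential(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """F-test of separate vs shared decay time for two 1-CDF exponential fits.

    Full model: each sample gets its own (A, τ) — 4 parameters.  Reduced
    model: amplitudes free but a single shared τ — 3 parameters.  The
    statistic is the usual extra-sum-of-squares ratio on the pooled
    fitting points.
    """
    from scipy.optimize import curve_fit

    ta, ya = empirical_survival(a)
    tb, yb = empirical_survival(b)
    fa = fit_exponential_survival(ta, ya, tau0=float(a.mean()))
    fb = fit_exponential_survival(tb, yb, tau0=float(b.mean()))
    rss_full = fa.rss + fb.rss
    df_full = (ta.size + tb.size) - 4

    t_all = np.concatenate([ta, tb])
    y_all = np.concatenate([ya, yb])
    is_b = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])

    def shared(t, amp_a, amp_b, tau):
        amp = np.where(is_b > 0.5, amp_b, amp_a)
        return amp * np.exp(-t / tau)

    tau0 = float(np.concatenate([a, b]).mean())
    popt, _ = curve_fit(shared, t_all, y_all, p0=[1.0, 1.0, tau0], maxfev=10000)
    rss_red = float(np.sum((y_all - shared(t_all, *popt)) ** 2))
    df_red = t_all.size - 3
    if df_full <= 0 or rss_full <= 0:
        raise ValueError("degenerate samples for F-test")
    f_stat = ((rss_red - rss_full) / (df_red - df_full)) / (rss_full / df_full)
    p = float(stats.f.sf(f_stat, df_red - df_full, df_full))
    return float(f_stat), p
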