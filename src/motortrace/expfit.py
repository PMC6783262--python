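"""Exponential fits to empirical inverse cumulative distributions.

Run lengths, residence times and wall-pause durations are all summarized
the same way: form the empirical 1-CDF (survival function) of the pooled
positive values and fit A·exp(−t/τ) by unweighted least squares.  The
helpers here are shared by the model classes in :mod:`pause`,
:mod:`motility` and :mod:`wall`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["empirical_survival", "fit_exponential_survival", "ExpFit"]


def empirical_survival(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 1-CDF evaluated at the sorted unique sample values.

    The survival value assigned to a unique value t is the midpoint of the
    empirical step there, (#{x > t} + #{x = t}/2)/n — the Hazen plotting
    position.  Each tied group contributes one unweighted fitting point.
    The midpoint convention keeps least-squares exponential decay-time
    estimates essentially unbiased even at small n, where the ≥ and >
    conventions bias the decay time up or down respectively.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    n = values.size
    t, counts = np.unique(values, return_counts=True)
    greater = counts[::-1].cumsum()[::-1] - counts
    s = (greater + 0.5 * counts) / n
    return t, s


def _exp_decay(t, amp, tau):
    return amp * np.exp(-t / tau)


class ExpFit:
    """Result of a single-exponential fit A·exp(−t/τ) to (t, y) points."""

    __slots__ = ("amp", "tau", "amp_stderr", "tau_stderr", "rss", "n_points")

    def __init__(self, amp, tau, amp_stderr, tau_stderr, rss, n_points):
        self.amp = float(amp)
        self.tau = float(tau)
        self.amp_stderr = float(amp_stderr)
        self.tau_stderr = float(tau_stderr)
        self.rss = float(rss)
        self.n_points = int(n_points)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _exp_decay(np.asarray(t, dtype=float), self.amp, self.tau)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpFit(amp={self.amp:.4g}±{self.amp_stderr:.2g}, "
            f"tau={self.tau:.4g}±{self.tau_stderr:.2g}, n={self.n_points})"
        )


def fit_exponential_survival(
    t: np.ndarray,
    y: np.ndarray,
    tau0: float | None = None,
    amp0: float = 1.0,
    fix_amp: bool = False,
) -> ExpFit:
    """Unweighted least-squares fit of A·exp(−t/τ) to survival points.

    Raises ValueError when the points carry no exponential structure
    (fewer than 3 distinct abscissae or zero spread).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if np.unique(t).size < 3:
        raise ValueError("degenerate 1-CDF: fewer than 3 distinct values")
    if tau0 is None:
        tau0 = float(np.average(t, weights=np.maximum(y, 1e-12)))
        if tau0 <= 0:
            tau0 = float(np.mean(t)) or 1.0
    if fix_amp:
        popt, pcov = curve_fit(
            lambda tt, tau: _exp_decay(tt, amp0, tau), t, y, p0=[tau0], maxfev=10000
        )
        amp, tau = amp0, popt[0]
        amp_err, tau_err = 0.0, float(np.sqrt(np.diag(pcov))[0])
    else:
        popt, pcov = curve_fit(_exp_decay, t, y, p0=[amp0, tau0], maxfev=10000)
        amp, tau = popt
        errs = np.sqrt(np.diag(pcov))
        amp_err, tau_err = float(errs[0]), float(errs[1])
    if tau <= 0:
        raise ValueError("exponential fit converged to non-positive decay time")
    rss = float(np.sum((y - _exp_decay(t, amp, tau)) ** 2))
    return ExpFit(amp, tau, amp_err, tau_err, rss, t.size)
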