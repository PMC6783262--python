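# Methods

## Stepping simulator

The generator emulates a motor walking along one microtubule protofilament
axis. It draws dwell times from a two-state exponential mixture: before
each 8 nm forward step the dwell comes from the paused state
(mean 0.59 s) with probability q = ρ·d (ρ the target pause density in
µm⁻¹, d = 0.008 µm), otherwise from the processive state (mean 0.015 s).
This per-step mixture is one of several ways two dwell states could
interleave; it was chosen because it gives a well-defined pauses-per-µm
ground truth against which the pause-density estimator can be scored, and
it makes the degenerate case (equal dwell means) collapse exactly to a
single-exponential stepper.

The continuous-time path is resampled to the camera frame grid by
sample-and-hold (position after the last step at or before each frame
time), mimicking an instantaneously stepping emitter imaged at 10 Hz, then
perturbed with i.i.d. zero-mean Gaussian noise of SD σ in both x and y.
Defaults: 10 Hz, σ = 30 nm (middle of the 28–57 nm per-frame range implied
by typical quantum-dot localization errors of 20–40 nm in σ_x′ units), and
5 s per trace — about 2 µm of travel at the default stepping parameters,
comparable to measured single-kinesin run lengths. Each trace records its
ground truth (step times, pause flags), and (number of steps) × 8 nm
equals the noiseless net displacement exactly.

What the generator does **not** model: photophysics (blinking, bleaching),
camera integration/PSF/pixelation, back-stepping or detachment during a
trace, protofilament geometry, and drift. Parameter recovery on these
simulations therefore demonstrates that the analysis inverts its own
generating model at realistic noise; it does not certify performance
against artifacts the generator omits.

## Preprocessing

Tracks are projected onto the microtubule axis by a total-least-squares
line fit (principal eigenvector of the positional covariance), which is
symmetric in x and y. The on-axis coordinate is oriented so net
displacement is positive; this convention does not claim to recover MT
polarity. The projection preserves total squared positional deviation.

Quality control rejects tracks with any frame-to-frame 2D displacement
above 100 nm (a linking-error signature). The filter is applied **after**
window averaging: at realistic noise (σ ≈ 30 nm per axis) the raw
frame-to-frame noise displacement alone has SD ≈ 60 nm and would reject
essentially every genuine track, while smoothing suppresses noise by √w
and leaves true linking jumps visible.

Smoothing is a centered moving mean of odd width w, with shrunken windows
at the edges so trace length — and hence total residence time — is
conserved. Defaults w = 3 frames and bin = 80 nm were chosen by the
simulation-driven calibration described below: the bin is ten steps wide
and more than twice the typical σ_x′, so noise-induced bin re-entry is
rare.

## Residence-time pause analysis

Each smoothed track is divided into half-open distance bins
[k·bin, (k+1)·bin) anchored at the track's minimum on-axis position (tracks
have arbitrary origins, so a global anchor would be meaningless). The
residence time of a bin is the frame count in the bin times the frame
interval; zero bins are dropped.

Non-zero residence times pooled over a condition are summarized by their
empirical 1-CDF, evaluated at the unique sorted values with Hazen midpoint
plotting positions ((#{x > t} + #{x = t}/2)/n). The midpoint convention
matters: with the ≥ convention, unweighted least-squares exponential fits
overestimate the decay time by ~10% at n ≈ 10–20, while midpoint positions
are essentially unbiased at all sample sizes checked (n = 11 to 10⁴).

The 1-CDF is fit with A·e^(−t/τ_fast) by unweighted least squares
(`scipy.optimize.curve_fit`). For a two-exponential survival curve the
residuals of this single-exponential fit are negative at short times and
positive in the tail; the slow component B·e^(−t/τ_slow) is fit to the
longest contiguous run of positive residuals, **starting at the residual
maximum**. The rising shoulder below the peak is contamination from the
fast-fit overshoot, not slow decay: including it flattens the fitted
exponential and inflates τ_slow by ~75% at the reference condition,
whereas fitting from the peak recovers the generating pause duration to
within a few percent. If no adequate positive tail exists, the fit fails
to converge, or τ_slow ≤ τ_fast, the result reports "no slow component"
with zero pause density.

Pause density is defined as B · N_bins / L, with N_bins the pooled count
of non-zero bins and L the summed on-axis track length in µm. B estimates
the fraction of bins containing a pause, so B·N_bins estimates the number
of paused bins and dividing by L converts to pauses per µm. In simulation
this definition tracks the true pause density 1:1 (0.97 recovered at 1.0
true, averaged over seeds) and doubles when the true density doubles.

Interpretation note: τ_fast from this procedure is the bin transit time
(bin/velocity, quantized to frames), not the molecular stepping dwell.

### Calibration

`calibrate_parameters` runs the full pipeline over a (window, bin) grid on
paired pause-free and pause-containing ensembles, reporting per pair the
spurious-pause rate on null data, the 95th percentile of null pause
densities (the false-positive bound used by the null-control check), and
the relative bias of recovered τ_slow. It selects the pair minimizing
|bias| subject to a spurious rate below 5%. At the shipped defaults the
spurious rate on pause-free data is 0 across replicates.

## Localization error

σ_x′ is the sample SD of the half first-differences
x′_i = (x_{i+1} − x_i)/2 of the unsmoothed on-axis positions. The
half-difference removes constant offsets and constant-velocity drift
exactly and passes white noise with variance σ²/2, so σ_x′ = σ/√2 for
i.i.d. Gaussian noise. Both σ_x′ (reported as-is) and the implied
per-frame σ̂ = σ_x′·√2 are exposed, because the literature is ambiguous
about which convention a printed "localization error" refers to; nothing
downstream depends on the choice.

## Motility statistics

Mobile fraction counts tracks with net on-axis displacement at or above a
threshold (default 250 nm, motivated by the shortest processive runs
resolvable in the data the method targets) over all tracks. Note the
threshold censors genuinely mobile motors whose exponential run falls
short of it, so for an ensemble with immobile fraction f and run-length
decay λ the expected mobile fraction is (1 − f)·e^(−0.25/λ), not 1 − f.

Velocity is net displacement over trace duration — the kymograph endpoint
convention, pauses included — so it decreases monotonically with pause
density. Run lengths are fit like all other positive variables here
(1-CDF, single exponential, unweighted least squares); both the decay
constant λ and the half-life ln 2·λ are always reported, since both
conventions are in use. No censoring correction is applied for runs ending
at microtubule ends.

Condition comparisons: Welch two-tailed t-test (scipy), two-proportion
z-test (statsmodels), and an extra-sum-of-squares F-test that compares
separate exponential fits of two samples' 1-CDFs (4 parameters) against a
shared-decay fit (3 parameters) on the pooled fitting points. At the
sample sizes typical of wall-pause data (n ≈ 16 vs 11, means 3.8 vs
7.8 s) this F-test detects the difference in a majority of simulated
replicates at α = 0.05.

## Obstacle density

Two estimators per microtubule: spots/µm (reliable while spots are
resolvable) and (total intensity / single-QD intensity)/µm (needed once
spots overlap, when counting saturates and the intensity estimate is an
upper envelope of it). The automatic crossover at 2 µm⁻¹ is a default,
not a measurement; both estimators are always available individually.
Inputs are assumed background-corrected, and the single-QD intensity is a
required calibration input measured from isolated spots.

## Wall-encounter classification

A bead arriving at the wall is classified from its intensity and position
trace: a relative drop ≥ 30% between pre- and post-wall median intensity
marks the rotation to the far side of the microtubule (light-to-dark); a
net advance ≥ 100 nm beyond the wall plateau marks resumed forward motion.
Resumption with dwell ≤ 1 s is a pass, > 1 s a pause-pass (the dwell is
measured from wall arrival to the first frame past the plateau, so it is
quantized to one frame interval); no resumption is detach if the trace
ends within ~3 frames of arrival, stuck if the bead persists unrotated.
The 30% drop and 100 nm advance are explicit reconstructions of what an
observer reads qualitatively from kymographs — tunable, with classifier
recovery validated on synthetic ensembles (tallies within binomial error,
refit pause mean within 2 SE). Because pause-pass requires dwell > 1 s,
short true dwells are relabelled pass; the exponential refit of pause-pass
dwells is unaffected in its decay constant (memorylessness), only in
amplitude.

## Problem sizes and numerical conventions

The recovery checks use 200 traces × 10–20 seeded replicates for pause
analysis (≈ 350 µm of track per replicate), 1000 replicates for the
small-n exponential fits, and 100 replicates for the null false-positive
control; these sizes put Monte Carlo error well below the effect sizes
being checked while keeping the whole suite around ten seconds. All
internal lengths are nm and times s; µm appears only at reporting
boundaries. Random streams are `numpy.random.default_rng` generators
seeded explicitly; identical (config, seed) pairs reproduce track tables
byte-for-byte.

## Known limitations

- The pause-density conversion assumes at most one pause per bin;
  at densities approaching 1/bin (≈ 12 µm⁻¹ at 80 nm) it saturates.
- τ_slow recovery carries a small negative bias (≈ −5% at the reference
  condition), from pauses split across bin boundaries by smoothing drift.
- The axis fit assumes a straight microtubule over the track extent;
  curved filaments would inflate s_perp and blur bins.
- Pauses shorter than the bin transit time (~0.15 s at defaults) are
  largely absorbed into the fast component and do not count toward pause
  density.
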