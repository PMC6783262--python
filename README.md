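# motortrace

Post-processing and simulation for single-particle tracking of microtubule
motor proteins (kinesin-1, cytoplasmic dynein, dynein–dynactin–BicD2).
Given particle trajectories from upstream detection/linking software,
`motortrace` answers the questions a motility study asks of them: how often
and how long does a motor pause, how far and how fast does it run, how many
obstacles decorate the microtubule, and what happens when a multi-motor
cargo hits a wall-sized obstacle.

Because pause detection from camera-limited, noisy trajectories is easy to
get wrong, the package ships a ground-truth stepping simulator and treats
parameter recovery on simulated data as its test surface.

## The model

A motor takes *d* = 8 nm unidirectional steps with exponentially
distributed dwell times drawn from two states: a fast processive state
(mean τ_fast = 0.015 s) and a slow paused state (mean τ_pause = 0.59 s),
entered with per-step probability *q* = ρ·*d* where ρ is the pause density
in µm⁻¹. The continuous path is resampled to the camera rate (10 Hz,
sample-and-hold) and i.i.d. Gaussian localization noise σ is added.

The analysis inverts this: tracks are projected onto the microtubule long
axis (total-least-squares line fit), smoothed with a centered running
window, and divided into distance bins; the residence time per bin is
(frames in bin) × Δt. Pooled non-zero residence times *t* follow an
approximately two-exponential survival curve. The empirical 1-CDF is fit
with A·e^(−t/τ_fast); the residuals of that fit are positive in the tail
and are fit with B·e^(−t/τ_slow), giving

- **pause duration** = τ_slow,
- **pause density** = B · N_bins / L  (pauses per µm, with N_bins the
  number of pooled non-zero bins and L the total track length).

Run lengths, wall-pause durations and localization error use the standard
estimators of the field: 1-CDF single-exponential fits (decay constant λ
and half-life ln 2·λ both reported) and the high-pass half-difference
x′_i = (x_{i+1} − x_i)/2, whose SD σ_x′ equals σ/√2 for white noise.

## Worked example

```python
from motortrace import StepperConfig, simulate_ensemble, analyze_trajectories

cfg = StepperConfig(pause_density_true=1.0, n_traces=200, seed=1)
trajs, truths = simulate_ensemble(cfg)
print(analyze_trajectories(trajs).summary())
```

```
Residence-time pause analysis
==============================================
tracks                                     143
pooled residence times                    3548
total track length (µm)                 279.80
tau_fast (s)                     0.120 ± 0.004
pause duration (s)               0.620 ± 0.024
slow amplitude                   0.075 ± 0.004
pause density (µm⁻¹)                     0.948
==============================================
```

The generating ensemble paused at 1 µm⁻¹ with 0.59 s mean pauses (realized
ground truth for this seed: 0.92 pauses/µm); the pipeline recovers a
0.62 s pause duration and 0.95 pauses/µm from the noisy, camera-sampled
traces alone. `tau_fast` ≈ 0.12 s is the transit time through an 80 nm bin
at the processive speed, not a molecular dwell. 57 of 200 tracks were
dropped by the 100 nm jump-exclusion QC.

The same objects work on real track tables
(`read_tracks("tracks.csv")` → the same pipeline), and every stage is also
exposed on the command line:

```bash
motortrace simulate --seed 1 --out tracks.csv --truth truth.json
motortrace pauses   --in tracks.csv --bin 80 --window 3 --out pauses.json
motortrace locerr   --in tracks.csv --out locerr.csv
motortrace motility --in tracks.csv --min-disp 250 --out summary.json
motortrace density  --in mts.csv --out density.csv
motortrace wall     --in events.csv --manifest walls.csv --out outcomes.json
```

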