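"""Mobile fraction, velocity, run-length fits and condition comparisons."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from motortrace import (
    MotilitySummary,
    RunLengthModel,
    compare_conditions,
    compute_mobile_fraction,
    compute_velocity,
    fit_run_length,
    normalize_to_control,
    project_onto_axis,
    simulate_run_length_ensemble,
    summarize_condition,
)
from motortrace.tracks import ProjectedTrack


def make_projected(s, dt=0.1, tid="m"):
    s = np.asarray(s, dtype=float)
    return ProjectedTrack(tid, np.arange(len(s)) * dt, s, np.zeros_like(s))


def linear_track(total_nm, n=20):
    return make_projected(np.linspace(0, total_nm, n))


class TestMobileFraction:
    def test_three_of_ten(self):
        tracks = [linear_track(d) for d in [300, 400, 500] + [100] * 7]
        n_mobile, n_total, frac = compute_mobile_fraction(tracks)
        assert (n_mobile, n_total, frac) == (3, 10, 0.3)

    def test_zero_threshold_means_all_mobile(self):
        tracks = [linear_track(d) for d in (1, 10, 100)]
        assert compute_mobile_fraction(tracks, min_displacement=0.0)[2] == 1.0

    def test_simulated_immobile_fraction(self):
        """Mobile fraction = (1 − immobile) × P(run ≥ threshold): mobile
        traces whose exponential run falls short of 250 nm are censored."""
        trajs = simulate_run_length_ensemble(
            2.1, 1000, immobile_fraction=0.3, seed=5, loc_error_sigma=10.0
        )
        tracks = [project_onto_axis(t) for t in trajs]
        frac = compute_mobile_fraction(tracks)[2]
        expected = 0.7 * np.exp(-0.25 / 2.1)
        assert frac == pytest.approx(expected, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_mobile_fraction([])

    @given(st.floats(0.0, 400.0), st.floats(0.0, 400.0))
    def test_monotone_in_threshold(self, lo, extra):
        tracks = [linear_track(d) for d in (50, 150, 250, 350, 450)]
        f_lo = compute_mobile_fraction(tracks, min_displacement=lo)[2]
        f_hi = compute_mobile_fraction(tracks, min_displacement=lo + extra)[2]
        assert f_hi <= f_lo


class TestVelocity:
    def test_endpoint_convention(self):
        track = make_projected(np.linspace(0, 1000, 21))  # 1000 nm in 2 s
        assert compute_velocity(track) == pytest.approx(500.0)

    def test_stepper_speed_without_pauses(self):
        from motortrace import StepperConfig, simulate_ensemble

        cfg = StepperConfig(pause_density_true=0.0, n_traces=50, seed=2)
        trajs, _ = simulate_ensemble(cfg)
        v = np.mean([compute_velocity(project_onto_axis(t)) for t in trajs])
        assert v == pytest.approx(8.0 / 0.015, rel=0.05)

    def test_pauses_lower_endpoint_velocity(self):
        from motortrace import StepperConfig, simulate_ensemble

        speeds = []
        for density in (0.0, 1.0, 3.0):
            cfg = StepperConfig(pause_density_true=density, n_traces=80, seed=4)
            trajs, _ = simulate_ensemble(cfg)
            speeds.append(
                np.mean([compute_velocity(project_onto_axis(t)) for t in trajs])
            )
        assert speeds[0] > speeds[1] > speeds[2]


class TestRunLengthFit:
    def test_recovers_generating_decay(self, rng):
        lam, half, err = fit_run_length(rng.exponential(2.1, 10_000))
        assert lam == pytest.approx(2.1, rel=0.05)
        assert half == pytest.approx(np.log(2) * lam, rel=1e-9)

    def test_agreement_with_mle(self, rng):
        sample = rng.exponential(1.5, 10_000)
        lam = fit_run_length(sample)[0]
        assert lam == pytest.approx(sample.mean(), rel=0.05)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            RunLengthModel(np.full(100, 2.0)).fit()

    def test_too_small_or_nonpositive_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 30"):
            RunLengthModel(rng.exponential(1.0, 10))
        with pytest.raises(ValueError, match="positive"):
            RunLengthModel(np.concatenate([rng.exponential(1.0, 40), [-1.0]]))

    def test_summary_prints_both_conventions(self, rng):
        text = RunLengthModel(rng.exponential(2.0, 500)).fit().summary()
        assert "decay constant" in text and "half-life" in text


def make_summary(**kw):
    base = dict(
        condition="c", n_total=100, n_mobile=80, mobile_fraction=0.8,
        velocity_mean=500.0, velocity_sd=50.0, run_length_decay=2.0,
        run_length_halflife=np.log(2) * 2.0, fit_error=0.1,
    )
    base.update(kw)
    return MotilitySummary(**base)


class TestNormalization:
    def test_control_over_itself_is_one(self):
        control = make_summary()
        ratios = normalize_to_control(control, control)
        assert all(v == 1.0 for v in ratios.values())

    def test_ninety_percent_mobile_fraction_reduction(self):
        obs = make_summary(mobile_fraction=0.08)
        control = make_summary(mobile_fraction=0.8)
        assert normalize_to_control(obs, control)["mobile_fraction"] == pytest.approx(0.10)

    def test_zero_control_metric_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_to_control(make_summary(), make_summary(velocity_mean=0.0))


class TestComparisons:
    def test_identical_samples_t_test(self, rng):
        a = rng.normal(0, 1, 50)
        stat, p = compare_conditions(a, a.copy(), "t_test")
        assert p == pytest.approx(1.0)

    def test_equal_proportions_z_zero(self):
        stat, p = compare_conditions((10, 100), (10, 100), "z_proportions")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_f_test_power_on_printed_wall_pause_means(self):
        """Exponentials with means 3.8 vs 7.8 at n = (16, 11): detected in
        a majority of replicates at α = 0.05."""
        rng = np.random.default_rng(8)
        hits = 0
        reps = 60
        for _ in range(reps):
            a = rng.exponential(3.8, 16)
            b = rng.exponential(7.8, 11)
            _, p = compare_conditions(a, b, "f_test_expfits")
            hits += p < 0.05
        assert hits > reps / 2

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            compare_conditions([1, 2], [3, 4], "wilcoxon")


class TestConditionSummary:
    def test_summarize_simulated_condition(self):
        trajs = simulate_run_length_ensemble(
            2.1, 400, immobile_fraction=0.2, seed=9, loc_error_sigma=10.0
        )
        tracks = [project_onto_axis(t) for t in trajs]
        s = summarize_condition(tracks, condition="test")
        assert s.n_total == 400
        assert s.mobile_fraction == pytest.approx(0.8 * np.exp(-0.25 / 2.1), abs=0.06)
        assert s.run_length_decay == pytest.approx(2.1, rel=0.25)
        assert s.run_length_halflife == pytest.approx(
            np.log(2) * s.run_length_decay, rel=1e-9
        )
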