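"""State statistics, transitions, kymographs and heartbeat QC."""

import numpy as np
import pytest

from orbitrack import (compare_states, kymograph, qc_heartbeat, subset_fit,
                       state_statistics, transition_analysis)
from orbitrack.phases import MotionPhase


def make_phase(state, start, duration, velocity=0.5):
    direction = "antero" if state.endswith("antero") else "retro"
    speed_class = state.split("_")[0]
    disp = velocity * duration
    p = MotionPhase(
        start=start, end=start + duration, start_index=0, end_index=1,
        direction=direction, duration=duration, xy_displacement=disp,
        velocity=velocity, x_steps=np.full(10, 5.0), y_steps=np.zeros(10),
        speed_class=speed_class,
    )
    return p


class TestSubsetFit:
    def test_identical_subsets_have_zero_spread(self, rng):
        est, sd, fits = subset_fit(np.full(200, 2.5), "exponential", rng)
        assert est == pytest.approx(2.5)
        assert sd == 0.0
        assert len(fits) == 10

    def test_exponential_decay_recovery_within_bootstrap_error(self):
        rng = np.random.default_rng(8)
        tau, n = 2.5, 330
        data = rng.exponential(tau, n)
        est, _, _ = subset_fit(data, "exponential", rng)
        # parametric-bootstrap oracle for the sampling error of the estimator
        boot = [rng.exponential(tau, n).mean() for _ in range(300)]
        se = np.std(boot)
        assert abs(est - tau) < 4 * se

    def test_gaussian_model_estimates_the_center(self):
        rng = np.random.default_rng(9)
        est, sd, _ = subset_fit(rng.normal(0.62, 0.09, 300), "gaussian", rng)
        assert est == pytest.approx(0.62, abs=0.02)

    def test_small_samples_fall_back_to_raw_moments(self, rng):
        with pytest.warns(UserWarning, match="too few"):
            est, sd, _ = subset_fit(np.array([1.0, 2.0, 3.0]), "gaussian", rng)
        assert est == pytest.approx(2.0)

    def test_t_test_separates_distinct_parameters(self, rng):
        r = np.random.default_rng(1)
        _, _, fa = subset_fit(r.normal(0.62, 0.09, 300), "gaussian", rng)
        _, _, fb = subset_fit(r.normal(0.36, 0.08, 300), "gaussian", rng)
        assert compare_states(fa, fb) < 1e-6


class TestStateStatistics:
    def test_stationary_steps_fit_centered_gaussian(self, rng):
        r = np.random.default_rng(2)
        phases = [make_phase("fast_antero", 10 * i, 2.0, 0.6) for i in range(30)]
        summary = state_statistics(phases, rng, stationary_x_steps=r.normal(0.0, 3.9, 5000))
        row = summary[(summary.state == "stationary")].iloc[0]
        assert row.estimate == pytest.approx(0.0, abs=0.2)
        assert row.estimate_sd == pytest.approx(3.9, rel=0.05)

    def test_summary_has_all_quantities_per_state(self, rng):
        phases = [make_phase("fast_antero", 10 * i, 2.0, 0.6) for i in range(30)]
        phases += [make_phase("slow_retro", 500 + 10 * i, 0.5, 0.4) for i in range(25)]
        summary = state_statistics(phases, rng)
        got = set(map(tuple, summary[["state", "quantity"]].to_numpy()))
        for state in ("fast_antero", "slow_retro"):
            for qty in ("duration_s", "xy_displacement_um", "xy_velocity_um_s",
                        "x_orbit_displacement_nm"):
                assert (state, qty) in got


class TestTransitions:
    def test_same_state_pair_books_one_fast_fast_pause(self):
        phases = [make_phase("fast_antero", 0.0, 2.0),
                  make_phase("fast_antero", 5.0, 2.0)]
        table = transition_analysis(phases)
        assert table.counts.loc["fast_antero", "fast_antero"] == 1
        assert list(table.pauses["fast-fast"]) == [pytest.approx(3.0)]

    def test_direction_change_split_by_pause_length(self):
        phases = [
            make_phase("fast_antero", 0.0, 2.0),
            make_phase("slow_retro", 3.0, 0.5),      # 1 s pause, change
            make_phase("slow_retro", 5.0, 0.5),      # 1.5 s pause, no change
            make_phase("slow_antero", 30.0, 0.5),    # 24.5 s pause, change
        ]
        table = transition_analysis(phases)
        p_short, n_short = table.direction_change["short"]
        p_long, n_long = table.direction_change["long"]
        assert (n_short, n_long) == (2, 1)
        assert p_short == pytest.approx(0.5)
        assert p_long == pytest.approx(1.0)

    def test_markov_phase_sequence_recovered_within_binomial_error(self):
        rng = np.random.default_rng(6)
        states = ["fast_antero", "slow_antero", "slow_retro"]
        T = {"fast_antero": [0.6, 0.2, 0.2],
             "slow_antero": [0.5, 0.3, 0.2],
             "slow_retro": [0.5, 0.2, 0.3]}
        seq = ["fast_antero"]
        for _ in range(1500):
            seq.append(states[rng.choice(3, p=T[seq[-1]])])
        phases = [make_phase(s, 10.0 * i, 2.0) for i, s in enumerate(seq)]
        table = transition_analysis(phases)
        probs = table.probabilities
        for src, row in T.items():
            n = table.counts.loc[src].sum()
            for dst, p_true in zip(states, row):
                sigma = np.sqrt(p_true * (1 - p_true) / n)
                assert abs(probs.loc[src, dst] - p_true) < 3 * sigma

    def test_unclassified_phases_rejected(self):
        a = make_phase("fast_antero", 0.0, 2.0)
        b = make_phase("fast_antero", 5.0, 2.0)
        b.speed_class = None
        with pytest.raises(ValueError):
            transition_analysis([a, b])

    def test_no_pauses_gives_empty_classes(self):
        table = transition_analysis([make_phase("fast_antero", 0.0, 2.0)])
        assert all(len(v) == 0 for v in table.pauses.values())


class TestKymograph:
    def test_slopes_equal_phase_velocities(self):
        dt = 0.01
        t = np.arange(0, 4, dt)
        x = np.where(t < 2, 500.0 * t, 1000.0)  # 0.5 um/s then stationary
        pos = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        kymo = kymograph(t, pos)
        moving = kymo[kymo.t_s < 2]
        slope = np.polyfit(moving.t_s, moving.x_um, 1)[0]
        assert slope == pytest.approx(0.5, rel=0.01)
        still = kymo[kymo.t_s >= 2]
        assert still.x_um.std() == pytest.approx(0.0, abs=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            kymograph(np.array([]), np.zeros((0, 3)))


class TestHeartbeatQC:
    def test_white_noise_not_flagged(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 20, 0.01)
        pos = np.column_stack([t * 500.0, rng.normal(0, 5, len(t)), np.zeros(len(t))])
        assert not qc_heartbeat(t, pos).flagged

    def test_2hz_lateral_oscillation_flagged_at_peak_frequency(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 20, 0.01)
        y = 50.0 * np.sin(2 * np.pi * 2.0 * t) + rng.normal(0, 5, len(t))
        pos = np.column_stack([t * 500.0, y, np.zeros(len(t))])
        report = qc_heartbeat(t, pos)
        assert report.flagged
        assert report.peak_frequency == pytest.approx(2.0, abs=0.1)
        assert report.peak_amplitude == pytest.approx(50.0, rel=0.2)

    def test_axial_oscillation_is_out_of_scope(self):
        t = np.arange(0, 20, 0.01)
        z = 100.0 * np.sin(2 * np.pi * 2.0 * t)
        pos = np.column_stack([t * 500.0, np.zeros(len(t)), z])
        assert not qc_heartbeat(t, pos).flagged

    def test_short_recordings_rejected(self):
        t = np.arange(0, 5, 0.01)
        with pytest.raises(ValueError):
            qc_heartbeat(t, np.zeros((len(t), 3)))
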