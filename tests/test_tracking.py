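"""Closed-loop feedback tracking: convergence, search, recentering, precision."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from orbitrack import (Emitter, OrbitConfig, TrackerState, feedback_step,
                       run_tracking, sector_means, spiral_search)
from orbitrack.psf import SectorCounts


def fit_sinusoid(t, x, p0):
    p, _ = curve_fit(lambda t, A, w, ph: A * np.sin(w * t + ph), t, x, p0=p0)
    return p


class TestFeedbackStep:
    def test_stationary_emitter_converges_in_three_orbits(self, psf, cfg, lut_f, lut_g):
        traj = run_tracking(lambda t: np.zeros(3), psf, cfg, None, duration=1.0,
                            lut_f=lut_f, lut_g=lut_g, initial_offset=(100.0, 0.0, 0.0))
        errors = np.linalg.norm(traj.positions, axis=1)
        assert np.all(errors[2:] < 1.0)

    def test_below_threshold_engages_search_mode(self, cfg, lut_f, lut_g):
        state = TrackerState()
        counts = SectorCounts(np.full((16, 2), 0.5), timestamp=0.0)  # 16 photons < 30
        rec = feedback_step(state, counts, cfg, lut_f, lut_g)
        assert not rec.tracked
        assert state.searching
        assert np.all(np.isnan(rec.position))

    def test_dark_orbits_halve_the_sampling_rate(self, psf, lut_f, lut_g):
        cfg2 = OrbitConfig(dark_orbit_factor=2, orbit_period=0.005, count_threshold=30)
        traj = run_tracking(lambda t: np.zeros(3), psf, cfg2, None, duration=1.0,
                            lut_f=lut_f, lut_g=lut_g)
        assert cfg2.sample_interval == pytest.approx(0.01)
        assert np.allclose(np.diff(traj.times), 0.01)

    def test_on_the_fly_bias_only_without_dark_orbits(self, psf, lut_f, lut_g):
        # with dark orbits the update is clean; back-to-back orbits carry the
        # first-sector bias of the on-the-fly position update
        kw = dict(duration=1.0, lut_f=lut_f, lut_g=lut_g, initial_offset=(100.0, 0.0, 0.0))
        clean = run_tracking(lambda t: np.zeros(3), psf,
                             OrbitConfig(dark_orbit_factor=2, count_threshold=30),
                             None, **kw)
        biased = run_tracking(lambda t: np.zeros(3), psf,
                              OrbitConfig(dark_orbit_factor=1, count_threshold=30),
                              None, **kw)
        assert abs(clean.positions[1, 0]) < 1e-3
        assert abs(biased.positions[1, 0]) > 1.0


class TestSpiralSearch:
    def test_probe_radius_is_non_decreasing(self, cfg):
        state = TrackerState(searching=True, search_origin=np.zeros(2))
        radii = []
        for _ in range(60):
            probe = spiral_search(state, cfg)
            radii.append(np.hypot(probe[0], probe[1]))
        assert np.all(np.diff(radii) >= -1e-9)

    def test_reacquires_emitter_within_one_extra_turn(self, psf, lut_f, lut_g):
        # threshold chosen above the count rate seen at the loss point so the
        # search must walk the spiral out to the emitter at 400 nm
        cfg2 = OrbitConfig(dark_orbit_factor=1, count_threshold=260.0)
        em = Emitter(brightness=1600.0)
        traj = run_tracking(lambda t: np.zeros(3), psf, cfg2, None, emitter=em,
                            duration=1.0, lut_f=lut_f, lut_g=lut_g,
                            initial_offset=(400.0, 0.0, 0.0))
        assert traj.status == "ok"
        assert np.any(traj.tracked)
        first = int(np.argmax(traj.tracked))
        assert 0 < first <= 4 * cfg2.spiral_points_per_turn
        tail = traj.positions[traj.tracked][6:]
        assert np.all(np.linalg.norm(tail, axis=1) < 1.0)

    def test_exhausted_spiral_declares_loss(self, psf, lut_f, lut_g):
        cfg2 = OrbitConfig(dark_orbit_factor=1, count_threshold=100.0,
                           spiral_max_radius=1000.0)
        em = Emitter(brightness=500.0)
        traj = run_tracking(lambda t: np.zeros(3), psf, cfg2, None, emitter=em,
                            duration=5.0, lut_f=lut_f, lut_g=lut_g,
                            initial_offset=(4000.0, 0.0, 0.0))
        assert traj.status == "lost"
        assert not np.any(traj.tracked)


class TestLongRangeRecentering:
    def test_crossing_threshold_triggers_event_and_dead_time(self, psf, cfg, lut_f, lut_g):
        v = 3000.0  # nm/s: reaches 10.1 um within ~3.4 s
        traj = run_tracking(lambda t: np.array([v * t, 0.0, 0.0]), psf, cfg,
                            None, duration=4.0, lut_f=lut_f, lut_g=lut_g)
        events = np.flatnonzero(traj.recenter_axis != "")
        assert len(events) == 1
        assert traj.recenter_axis[events[0]] == "x"
        gap = traj.times[events[0] + 1] - traj.times[events[0]]
        assert gap == pytest.approx(cfg.dead_time_x, abs=0.011)

    def test_no_event_inside_threshold(self, psf, cfg, lut_f, lut_g):
        traj = run_tracking(lambda t: np.array([2000.0 * t, 0.0, 0.0]), psf, cfg,
                            None, duration=4.0, lut_f=lut_f, lut_g=lut_g)
        assert np.all(traj.recenter_axis == "")

    def test_sample_fixed_coordinates_continuous_across_event(self, psf, cfg, lut_f, lut_g):
        v = 3000.0
        rng = np.random.default_rng(4)
        traj = run_tracking(lambda t: np.array([v * t, 0.0, 0.0]), psf, cfg,
                            rng, duration=5.0, lut_f=lut_f, lut_g=lut_g)
        event = int(np.flatnonzero(traj.recenter_axis != "")[0])
        resid = traj.positions[:, 0] - v * traj.times
        sigma = resid[: event - 5].std()
        before = resid[event - 20: event].mean()
        after = resid[event + 1: event + 21].mean()
        assert abs(after - before) < 2 * sigma + 1.0


class TestValidationProtocols:
    def test_precision_scales_as_inverse_sqrt_photons(self, psf, cfg, lut_f, lut_g):
        rng = np.random.default_rng(21)
        brightnesses = [200.0, 800.0, 3200.0]
        stds = []
        for b in brightnesses:
            traj = run_tracking(lambda t: np.zeros(3), psf, cfg, rng,
                                emitter=Emitter(brightness=b), duration=5.0,
                                lut_f=lut_f, lut_g=lut_g)
            stds.append(traj.positions[traj.tracked, 0].std())
        slope = np.polyfit(np.log(brightnesses), np.log(stds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.2)

    def test_sinusoid_amplitude_recovered_within_one_percent(self, psf, cfg, lut_f, lut_g):
        A, om = 2000.0, 0.25  # +/-2 um, 0.5 um/s peak velocity
        traj = run_tracking(lambda t: np.array([A * np.sin(om * t), 0.0, 0.0]),
                            psf, cfg, np.random.default_rng(7),
                            emitter=Emitter(brightness=1600.0),
                            duration=28.0, lut_f=lut_f, lut_g=lut_g)
        amp = fit_sinusoid(traj.times, traj.positions[:, 0], [1900, 0.26, 0.05])[0]
        assert amp == pytest.approx(A, rel=0.01)

    def test_extended_emitter_tracked_with_bounded_residuals(self, psf, cfg, lut_f, lut_g):
        A, om = 2000.0, 0.25
        truth = lambda t: np.array([A * np.sin(om * t), 0.0, 0.0])
        resid_stds = {}
        for length in (0.0, 600.0):
            traj = run_tracking(truth, psf, cfg, np.random.default_rng(7),
                                emitter=Emitter(brightness=1600.0, length=length),
                                duration=28.0, lut_f=lut_f, lut_g=lut_g)
            p = fit_sinusoid(traj.times, traj.positions[:, 0], [1900, 0.26, 0.05])
            resid = traj.positions[:, 0] - p[0] * np.sin(p[1] * traj.times + p[2])
            resid_stds[length] = resid.std()
        assert resid_stds[600.0] < 2 * resid_stds[0.0]

    def test_bleaching_reduces_count_rate_monotonically(self, psf, cfg, lut_f, lut_g):
        traj = run_tracking(lambda t: np.zeros(3), psf, cfg, None,
                            emitter=Emitter(brightness=1000.0, bleach_rate=0.01),
                            duration=3.0, lut_f=lut_f, lut_g=lut_g)
        assert np.all(np.diff(traj.counts) < 0)

    def test_short_ground_truth_rejected(self, psf, cfg, lut_f, lut_g):
        with pytest.raises(ValueError):
            run_tracking(lambda t: np.zeros(3), psf, cfg, None, duration=0.5,
                         lut_f=lut_f, lut_g=lut_g)
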