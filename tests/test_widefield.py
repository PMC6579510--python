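"""Wide-field movie analysis: mapping, background removal, detection, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orbitrack import (Blob, ImageStack, StateParams, WideFieldScene,
                       crossing_times, detect_stationary, fit_poly_map,
                       generate_state_trajectory, mean_segments,
                       occupancy_fractions, remove_moving,
                       render_widefield_movie)
from orbitrack.widefield import StationaryObject


def grid_points(n=5, span=100.0):
    g = np.linspace(0, span, n)
    return np.array([(x, y) for x in g for y in g])


class TestPolyMap:
    def test_identity_control_points(self):
        cam = grid_points()
        m = fit_poly_map(cam, cam)
        assert m.residual_rms == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(m(cam), cam, atol=1e-9)

    def test_pure_translation_recovered_exactly(self):
        cam = grid_points()
        trk = cam + np.array([500.0, -200.0])
        m = fit_poly_map(cam, trk)
        assert m.residual_rms == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(m(np.array([10.0, 20.0])), [510.0, -180.0], atol=1e-9)

    def test_second_order_warp_round_trip(self):
        cam = grid_points()
        trk = np.column_stack([
            10 + 130.0 * cam[:, 0] + 2.0 * cam[:, 1] + 0.05 * cam[:, 0] ** 2
            - 0.02 * cam[:, 0] * cam[:, 1],
            -5 + 1.5 * cam[:, 0] + 128.0 * cam[:, 1] + 0.03 * cam[:, 1] ** 2,
        ])
        m = fit_poly_map(cam, trk)
        assert m.residual_rms < 1e-6
        assert np.allclose(m(cam), trk, atol=1e-6)

    def test_degenerate_configuration_rejected(self):
        cam = np.column_stack([np.arange(25.0), np.zeros(25)])  # collinear
        with pytest.raises(ValueError, match="degenerate"):
            fit_poly_map(cam, cam)

    def test_too_few_points_rejected(self):
        cam = grid_points(n=3)[:8]
        with pytest.raises(ValueError, match="at least 12"):
            fit_poly_map(cam, cam)


class TestRemoveMoving:
    def test_static_stack_is_unchanged(self):
        frames = np.tile(np.random.default_rng(0).uniform(0, 50, (8, 12)), (15, 1, 1))
        out = remove_moving(ImageStack(frames), lag=10)
        assert np.allclose(out.frames, frames[:5])

    def test_disappearing_intensity_is_subtracted(self):
        frames = np.zeros((12, 4, 4))
        frames[0, 2, 2] = 100.0  # gone by frame 10
        out = remove_moving(ImageStack(frames), lag=10)
        assert out.frames[0, 2, 2] == pytest.approx(0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_never_increases_any_pixel(self, seed):
        frames = np.random.default_rng(seed).uniform(0, 100, (14, 6, 6))
        out = remove_moving(ImageStack(frames), lag=10)
        assert np.all(out.frames <= frames[:4] + 1e-12)

    def test_lag_longer_than_stack_rejected(self):
        with pytest.raises(ValueError):
            remove_moving(ImageStack(np.zeros((5, 4, 4))), lag=10)


class TestMeanSegments:
    def test_two_recenter_events_give_two_means(self):
        stack = ImageStack(np.zeros((30, 4, 4)), recenter_frames=[10, 20])
        assert len(mean_segments(stack)) == 2

    def test_constant_stack_mean_equals_any_frame(self):
        frame = np.arange(16.0).reshape(4, 4)
        stack = ImageStack(np.tile(frame, (7, 1, 1)))
        (mean, _), = mean_segments(stack)
        assert np.allclose(mean, frame)

    def test_piecewise_static_movie_averages_per_segment(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(10, 20, (4, 4))
        b = rng.uniform(10, 20, (4, 4))
        frames = np.concatenate([
            a + rng.normal(0, 1, (50, 4, 4)),
            b + rng.normal(0, 1, (50, 4, 4)),
        ])
        stack = ImageStack(frames, recenter_frames=[50])
        (mean_a, _), = mean_segments(stack)  # last segment dropped
        assert np.allclose(mean_a, a, atol=5 * 1.0 / np.sqrt(50))


class TestDetectStationary:
    def make_scene_stack(self, blob, rng=None, moving=0.0, duration=30.0, seed=5):
        gen = np.random.default_rng(seed)
        gt = generate_state_trajectory(StateParams(), duration, gen)
        scene = WideFieldScene(origin=(-2000.0, -4320.0),
                               stationary_blobs=[blob], moving_intensity=moving)
        stack = render_widefield_movie(scene, gt, rng=rng)
        return gt, scene, stack

    def test_blank_image_yields_no_objects(self):
        traj = np.column_stack([np.linspace(5, 100, 50), np.full(50, 32.0)])
        assert detect_stationary(np.zeros((64, 128)), traj, 135.0) == []

    def test_rendered_blob_round_trip_centroid_and_length(self):
        blob = Blob(5000.0, 0.0, 1000.0, 150.0)
        gt, scene, stack = self.make_scene_stack(blob, rng=np.random.default_rng(2))
        clean = remove_moving(stack)
        (mean_img, origin), = mean_segments(clean)
        traj_px = (gt.positions[:, :2] - origin) / scene.pixel_size
        objs = detect_stationary(mean_img, traj_px, scene.pixel_size, origin=origin)
        assert len(objs) == 1
        assert abs(objs[0].centroid[0] - 5000.0) < scene.pixel_size
        assert abs(objs[0].centroid[1] - 0.0) < scene.pixel_size
        assert abs(objs[0].length - 1000.0) < 2 * scene.pixel_size

    def test_blob_off_the_corridor_is_excluded(self):
        # bright blob 30 px from the trajectory: masked out by the 51x11 corridor
        blob = Blob(5000.0, 30 * 135.0, 1000.0, 200.0)
        gt, scene, stack = self.make_scene_stack(blob, rng=np.random.default_rng(2))
        clean = remove_moving(stack)
        (mean_img, origin), = mean_segments(clean)
        traj_px = (gt.positions[:, :2] - origin) / scene.pixel_size
        objs = detect_stationary(mean_img, traj_px, scene.pixel_size, origin=origin)
        assert objs == []


class TestOccupancy:
    def test_no_objects_means_all_free_and_normalized(self):
        states = np.array(["stationary"] * 40 + ["fast_antero"] * 60)
        report = occupancy_fractions(states, np.linspace(0, 1000, 100), [])
        assert report.n_samples["occupied"] == 0
        assert report.fractions["free"].sum() == pytest.approx(1.0)
        assert report.fraction("free", "fast_antero") == pytest.approx(0.6)

    def test_stationary_only_inside_object_zones(self):
        x = np.linspace(0.0, 10_000.0, 1000)
        obj = StationaryObject(centroid=np.array([5000.0, 0.0]), length=1000.0, pixel_extent=10)
        inside = (x >= 4000.0) & (x <= 6000.0)
        states = np.where(inside, "stationary", "fast_antero")
        report = occupancy_fractions(states, x, [obj], capture=500.0)
        assert report.fraction("occupied", "stationary") == pytest.approx(1.0)
        assert report.fraction("free", "fast_antero") == pytest.approx(1.0)

    def test_invariant_under_time_reversal(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.normal(5, 20, 500))
        states = rng.choice(["stationary", "fast_antero", "slow_retro"], 500)
        obj = StationaryObject(centroid=np.array([x.mean(), 0.0]), length=800.0, pixel_extent=5)
        a = occupancy_fractions(states, x, [obj]).fractions
        b = occupancy_fractions(states[::-1], x[::-1], [obj]).fractions
        assert np.allclose(a.to_numpy(dtype=float), b.to_numpy(dtype=float), equal_nan=True)


class TestCrossingTimes:
    def test_constant_speed_gives_uniform_bin_times(self):
        t = np.arange(0, 20, 0.01)
        x = 500.0 * t  # 0.5 um/s -> 0.2 s per 100 nm
        profile = crossing_times([(t, x)])
        inner = profile.crossing_times[0][2:-2]
        assert np.nanmedian(inner) == pytest.approx(0.2, rel=0.05)

    def test_injected_pause_flags_its_micron_bin(self):
        t = np.arange(0, 40, 0.01)
        x = np.where(t < 10, 500.0 * t,
                     np.where(t < 22, 5000.0, 5000.0 + 500.0 * (t - 22)))  # 12 s pause at 5 um
        profile = crossing_times([(t, x)])
        pause_bin = int((5000.0 - profile.coarse_edges[0]) // 1000)
        assert profile.slow_flags[0, pause_bin]
        assert profile.slow_fraction[pause_bin] == pytest.approx(1.0)

    def test_shared_pause_site_fraction_matches_construction(self):
        trajs = []
        for i in range(16):
            t = np.arange(0, 40, 0.01)
            if i < 12:  # 12 of 16 trajectories pause 12 s at x = 5 um
                x = np.where(t < 10, 500.0 * t,
                             np.where(t < 22, 5000.0, 5000.0 + 500.0 * (t - 22)))
            else:
                x = 500.0 * t
            trajs.append((t, x))
        profile = crossing_times(trajs)
        pause_bin = int((5000.0 - profile.coarse_edges[0]) // 1000)
        assert profile.slow_fraction[pause_bin] == pytest.approx(12 / 16)

    def test_unvisited_bins_are_missing_not_zero(self):
        t = np.arange(0, 10, 0.01)
        a = (t, 500.0 * t)            # covers 0..5 um
        b = (t, 20_000.0 + 500.0 * t) # covers 20..25 um
        profile = crossing_times([a, b])
        gap = (profile.bin_edges[:-1] > 6000) & (profile.bin_edges[:-1] < 19_000)
        assert np.all(np.isnan(profile.crossing_times[:, gap]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            crossing_times([])
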