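"""Synthetic wide-field scenes: stationary and moving fluorescent blobs.

Renders the camera channel that accompanies a tracking run: a 2 Hz movie of
Gaussian-blurred organelles on a constant background with Poisson photon
noise and Gaussian read noise.  Stationary blobs (resting mitochondria,
rendered as blurred line segments along the axon) persist in every frame;
the moving blob follows a ground-truth trajectory interpolated to frame
times.  Stage-recentering events shift the field of view, reproducing the
piecewise-stationary geometry that the wide-field analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion import GroundTruthTrajectory
from .widefield import ImageStack

__all__ = ["Blob", "WideFieldScene", "render_widefield_movie"]


@dataclass
class Blob:
    """A fluorescent object: center (nm), length along x (nm), peak intensity."""

    x: float
    y: float
    length: float = 0.0
    intensity: float = 100.0


@dataclass
class WideFieldScene:
    """Geometry, content and noise model of a synthetic wide-field movie.

    ``origin`` is the sample-fixed nm coordinate of pixel (0, 0).  The
    default pixel size matches the 135 nm raster of the photoactivation
    scan; the default 2 Hz frame rate matches the camera channel.
    """

    frame_rate: float = 2.0
    pixel_size: float = 135.0
    shape: tuple = (64, 128)            # (ny, nx) px
    origin: tuple = (0.0, 0.0)          # nm
    stationary_blobs: list = field(default_factory=list)
    moving_intensity: float = 200.0
    psf_sigma: float = 200.0            # nm, rendering blur
    background: float = 10.0            # counts / px / frame
    read_noise_sigma: float = 2.0       # counts rms
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        ny, nx = self.shape
        for b in self.stationary_blobs:
            px = (b.x - self.origin[0]) / self.pixel_size
            py = (b.y - self.origin[1]) / self.pixel_size
            if not (0 <= px < nx and 0 <= py < ny):
                raise ValueError(f"blob at ({b.x}, {b.y}) nm outside the field of view")


def _render_blob(img: np.ndarray, scene: WideFieldScene, origin: np.ndarray, blob: Blob) -> None:
    """Add a Gaussian-blurred line segment to an image (in place)."""
    ny, nx = img.shape
    px = scene.pixel_size
    s = scene.psf_sigma / px
    n_sub = max(1, int(np.ceil(blob.length / (0.5 * scene.psf_sigma))) + 1)
    offsets = (np.linspace(-0.5, 0.5, n_sub) * blob.length) if blob.length > 0 else np.array([0.0])
    cx = (blob.x + offsets - origin[0]) / px
    cy = np.full(n_sub, (blob.y - origin[1]) / px)
    xs = np.arange(nx)
    ys = np.arange(ny)
    gx = np.exp(-0.5 * ((xs[None, :] - cx[:, None]) / s) ** 2)  # (n_sub, nx)
    gy = np.exp(-0.5 * ((ys[None, :] - cy[:, None]) / s) ** 2)  # (n_sub, ny)
    img += (blob.intensity / n_sub) * np.einsum("ky,kx->yx", gy, gx)


def render_widefield_movie(
    scene: WideFieldScene,
    ground_truth: GroundTruthTrajectory,
    recenter_events: list | None = None,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render the camera movie accompanying a tracked trajectory.

    ``recenter_events`` is a list of ``(time_s, dx_nm, dy_nm)`` field-of-view
    shifts (the stage recenters the sample, so the scene origin moves by the
    absorbed galvo offset).  ``rng=None`` disables all noise.  The frame
    count is ``floor(duration * frame_rate)``; the scene frame rate must not
    exceed the trajectory sample rate.
    """
    if ground_truth.n_samples == 0:
        raise ValueError("empty trajectory")
    if scene.frame_rate > 1.0 / ground_truth.sample_interval:
        raise ValueError("frame rate exceeds the trajectory sample rate")
    n_frames = int(np.floor(ground_truth.duration * scene.frame_rate))
    if n_frames < 1:
        raise ValueError("trajectory too short for a single frame")
    events = sorted(recenter_events or [])
    frame_times = np.arange(n_frames) / scene.frame_rate
    moving_xy = ground_truth.position_at(frame_times)[..., :2].reshape(n_frames, 2)

    frames = np.empty((n_frames, *scene.shape))
    origins = np.empty((n_frames, 2))
    recenter_frames: list[int] = []
    origin = np.asarray(scene.origin, dtype=float).copy()
    ev = 0
    for i, t in enumerate(frame_times):
        while ev < len(events) and events[ev][0] <= t:
            origin += np.asarray(events[ev][1:3], dtype=float)
            if 0 < i < n_frames:
                recenter_frames.append(i)
            ev += 1
        img = np.full(scene.shape, float(scene.background))
        for blob in scene.stationary_blobs:
            _render_blob(img, scene, origin, blob)
        if scene.moving_intensity > 0:
            mover = Blob(moving_xy[i, 0], moving_xy[i, 1], 0.0, scene.moving_intensity)
            _render_blob(img, scene, origin, mover)
        if rng is not None:
            if scene.poisson:
                img = rng.poisson(img).astype(float)
            if scene.read_noise_sigma > 0:
                img += rng.normal(0.0, scene.read_noise_sigma, img.shape)
        frames[i] = img
        origins[i] = origin
    return ImageStack(
        frames=frames,
        frame_interval=1.0 / scene.frame_rate,
        pixel_size=scene.pixel_size,
        recenter_frames=sorted(set(recenter_frames)),
        origins=origins,
    )
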