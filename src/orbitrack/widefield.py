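"""Wide-field movie analysis: stationary organelles and their influence.

The wide-field channel records the axon around the tracked organelle at
2 Hz.  Stationary mitochondria are extracted by (i) suppressing moving
objects with a forward-difference subtraction, (ii) averaging the frames
between stage-recentering events (the field of view is only stationary
within a segment), (iii) thresholding the smoothed mean image at µ + 5σ
inside a 51 × 11 px corridor around the mapped trajectory and labeling
connected components.  Camera pixels map to tracking-stage nanometres via a
second-order polynomial transform calibrated on ≥25 control points.

Downstream, per-sample motion states are split by the local presence of a
stationary organelle (occupancy fractions) and crossing times per 100 nm of
axon reveal preferred pause sites (bins needing >10 s per µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "ImageStack",
    "PolyMap2D",
    "StationaryObject",
    "OccupancyReport",
    "CrossingProfile",
    "fit_poly_map",
    "remove_moving",
    "mean_segments",
    "detect_stationary",
    "occupancy_fractions",
    "crossing_times",
]


@dataclass
class ImageStack:
    """A wide-field movie: frames (t, y, x) with timing and geometry metadata.

    ``origins`` holds the sample-fixed nm coordinate of pixel (0, 0) per
    frame; it changes at stage-recentering events (``recenter_frames``).
    """

    frames: np.ndarray
    frame_interval: float = 0.5
    pixel_size: float = 135.0
    recenter_frames: list = field(default_factory=list)
    origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (t, y, x) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(np.diff(self.recenter_frames) <= 0):
            raise ValueError("recenter frame indices must be strictly increasing")
        if self.origins is None:
            self.origins = np.zeros((len(self.frames), 2))
        self.origins = np.asarray(self.origins, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class PolyMap2D:
    """Second-order bivariate polynomial map camera px -> tracking nm.

    ``coeffs[c]`` holds the 6 coefficients of output component c against the
    monomials (1, x, y, x², xy, y²); 12 coefficients in total.  An affine map
    is the special case with the three quadratic coefficients zero.
    """

    coeffs: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (2, 6):
            raise ValueError("coeffs must have shape (2, 6)")
        if not np.isfinite(self.residual_rms):
            raise ValueError("residual must be finite")

    @staticmethod
    def identity() -> "PolyMap2D":
        c = np.zeros((2, 6))
        c[0, 1] = 1.0
        c[1, 2] = 1.0
        return PolyMap2D(c)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = _design(pts) @ self.coeffs.T
        return out[0] if np.ndim(points) == 1 else out


def _design(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def fit_poly_map(camera_px: np.ndarray, tracking_nm: np.ndarray) -> PolyMap2D:
    """Least-squares second-order polynomial fit of paired control points.

    Calibrated experimentally from the back reflection of the tracking laser
    at ≥25 known camera locations; here any ≥12 well-spread pairs work.
    """
    cam = np.asarray(camera_px, dtype=float)
    trk = np.asarray(tracking_nm, dtype=float)
    if cam.shape != trk.shape or cam.ndim != 2 or cam.shape[1] != 2:
        raise ValueError("control points must be matched (n, 2) arrays")
    if len(cam) < 12:
        raise ValueError("need at least 12 control points (25 recommended)")
    A = _design(cam)
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("degenerate control-point configuration (rank-deficient)")
    coeffs, *_ = np.linalg.lstsq(A, trk, rcond=None)
    resid = trk - A @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return PolyMap2D(coeffs.T, rms)


def remove_moving(stack: ImageStack, lag: int = 10) -> ImageStack:
    """Suppress moving objects by forward-difference subtraction.

    Per pixel, intensity that disappears within ``lag`` frames is subtracted
    from the current frame (ΔI = I(t+lag) − I(t), kept only where negative;
    I_stationary = I + ΔI); brightening contributes nothing.  The final
    ``lag`` frames have no forward difference and are dropped.  Never
    increases any pixel value and is the identity on a static movie.
    """
    if lag >= stack.n_frames:
        raise ValueError(f"lag ({lag}) must be smaller than the stack length ({stack.n_frames})")
    frames = stack.frames
    delta = frames[lag:] - frames[:-lag]
    np.minimum(delta, 0.0, out=delta)
    out = frames[:-lag] + delta
    keep = stack.n_frames - lag
    return ImageStack(
        frames=out,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
        recenter_frames=[i for i in stack.recenter_frames if i < keep],
        origins=stack.origins[:keep],
    )


def mean_segments(stack: ImageStack) -> list[tuple[np.ndarray, np.ndarray]]:
    """Mean image per stationary field-of-view segment.

    A movie with m recentering events has m+1 segments; the mean after the
    last event (typically a long terminal stationary stretch) is discarded,
    so m means are returned.  Without recentering the single mean is kept.
    Returns ``(mean_image, origin_nm)`` pairs.
    """
    bounds = [0, *stack.recenter_frames, stack.n_frames]
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi > lo:
            means.append((stack.frames[lo:hi].mean(axis=0), stack.origins[lo].copy()))
    if len(means) > 1:
        means = means[:-1]
    return means


@dataclass
class StationaryObject:
    """A resting mitochondrion detected in the wide-field channel."""

    centroid: np.ndarray      # (x, y) nm, tracking frame
    length: float             # nm, extent along the axon axis
    pixel_extent: int         # component area, px
    segment_index: int = 0

    def interval(self, capture: float = 0.0) -> tuple[float, float]:
        """Occupied x interval (nm), optionally dilated by a capture distance."""
        half = 0.5 * self.length + capture
        return self.centroid[0] - half, self.centroid[0] + half


def _corridor_mask(shape: tuple, traj_px: np.ndarray, half_extent: tuple = (25, 5)) -> np.ndarray:
    """Union of 51 x 11 px boxes (half-widths 25 in x, 5 in y) around the trajectory."""
    mask = np.zeros(shape, dtype=bool)
    hx, hy = half_extent
    pts = np.unique(np.round(traj_px).astype(int), axis=0)
    ny, nx = shape
    for cx, cy in pts:
        x0, x1 = max(0, cx - hx), min(nx, cx + hx + 1)
        y0, y1 = max(0, cy - hy), min(ny, cy + hy + 1)
        if x1 > x0 and y1 > y0:
            mask[y0:y1, x0:x1] = True
    return mask


def detect_stationary(
    mean_image: np.ndarray,
    traj_px: np.ndarray,
    pixel_size: float,
    origin: np.ndarray | tuple = (0.0, 0.0),
    poly_map: PolyMap2D | None = None,
    smooth: int = 5,
    n_sigma: float = 5.0,
    corridor_half_extent: tuple = (25, 5),
    psf_sigma: float = 200.0,
    segment_index: int = 0,
) -> list[StationaryObject]:
    """Stationary-object extraction from one segment mean image.

    The image is smoothed by a ``smooth`` px boxcar, binarized at the
    full-frame mean + ``n_sigma`` std, masked to the corridor around the
    mapped trajectory (camera px), and connected components are measured.
    Centroids are intensity-weighted on the background-subtracted image;
    lengths along the axon use a second-moment estimate deconvolved for the
    smoothing kernel and the optical blur ``psf_sigma`` (nm), which keeps the
    estimate close to the physical extent rather than the thresholded
    footprint.  Coordinates map to tracking nm through ``poly_map`` when
    given, else through ``origin + pixel_size * px``.
    """
    img = np.asarray(mean_image, dtype=float)
    sm = uniform_filter(img, size=smooth)
    thr = sm.mean() + n_sigma * sm.std()
    binary = sm > thr
    binary &= _corridor_mask(img.shape, np.atleast_2d(traj_px), corridor_half_extent)
    if not np.any(binary):
        return []
    labels = cc_label(binary)
    background = float(np.median(img))
    objects = []
    # variance added by the boxcar smoothing and the optical blur, px^2
    blur_var = (smooth**2 - 1) / 12.0 + (psf_sigma / pixel_size) ** 2
    pad = int(np.ceil(3.0 * np.sqrt(blur_var))) + 1
    ny, nx = img.shape
    for prop in regionprops(labels):
        # moments over a window extending past the thresholded footprint so
        # the blurred tails are not truncated; other components are masked out
        r0 = max(0, prop.bbox[0] - pad)
        c0 = max(0, prop.bbox[1] - pad)
        r1 = min(ny, prop.bbox[2] + pad)
        c1 = min(nx, prop.bbox[3] + pad)
        win = sm[r0:r1, c0:c1] - background
        lab_win = labels[r0:r1, c0:c1]
        win = np.where((lab_win == 0) | (lab_win == prop.label), win, 0.0)
        w = np.clip(win, 0.0, None)
        if w.sum() <= 0:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        cx = float(np.average(cols, weights=w))
        cy = float(np.average(rows, weights=w))
        var_x = float(np.average((cols - cx) ** 2, weights=w))
        length_px = np.sqrt(12.0 * max(var_x - blur_var, 0.0))
        length_nm = max(length_px, 1.0) * pixel_size
        if poly_map is not None:
            centroid = poly_map(np.array([cx, cy]))
        else:
            centroid = np.asarray(origin, dtype=float) + pixel_size * np.array([cx, cy])
        objects.append(StationaryObject(
            centroid=centroid,
            length=float(length_nm),
            pixel_extent=int(prop.area),
            segment_index=segment_index,
        ))
    return objects


@dataclass
class OccupancyReport:
    """State-time fractions split by local stationary-organelle presence."""

    fractions: pd.DataFrame   # index: state, columns: "occupied", "free"
    n_samples: dict

    def fraction(self, condition: str, state: str) -> float:
        return float(self.fractions.loc[state, condition])


def occupancy_fractions(
    states: np.ndarray,
    x_positions: np.ndarray,
    objects: list[StationaryObject],
    capture: float = 500.0,
) -> OccupancyReport:
    """Fraction of time per motion state, by local presence of a stationary object.

    A sample is *occupied* when its x position falls within an object's
    extent dilated by ``capture`` nm along the axon.  Fractions are
    normalized within each condition (each column sums to 1).
    """
    states = np.asarray(states)
    x = np.asarray(x_positions, dtype=float)
    if len(states) != len(x):
        raise ValueError("states and positions must align")
    occupied = np.zeros(len(x), dtype=bool)
    for obj in objects:
        lo, hi = obj.interval(capture)
        occupied |= (x >= lo) & (x <= hi)
    state_names = sorted(set(states.tolist()))
    frac = pd.DataFrame(index=state_names, columns=["occupied", "free"], dtype=float)
    for cond, mask in (("occupied", occupied), ("free", ~occupied)):
        n = int(mask.sum())
        for s in state_names:
            frac.loc[s, cond] = ((states == s) & mask).sum() / n if n else np.nan
    return OccupancyReport(
        fractions=frac, n_samples={"occupied": int(occupied.sum()), "free": int((~occupied).sum())}
    )


@dataclass
class CrossingProfile:
    """Per-position crossing times and slow-progress foci along the axon."""

    bin_edges: np.ndarray          # fine (100 nm) bin edges, nm
    crossing_times: np.ndarray     # (n_traj, n_bins) seconds, NaN where unvisited
    coarse_edges: np.ndarray       # 1 µm bin edges, nm
    slow_fraction: np.ndarray      # fraction of visiting trajectories >10 s per bin
    slow_flags: np.ndarray         # (n_traj, n_coarse) booleans, False where unvisited


def crossing_times(
    trajectories: list[tuple[np.ndarray, np.ndarray]],
    bin_size: float = 100.0,
    coarse_size: float = 1000.0,
    slow_threshold: float = 10.0,
) -> CrossingProfile:
    """Time each trajectory needs to traverse fixed bins of the axon axis.

    ``trajectories`` is a list of ``(times_s, x_nm)`` pairs sharing an axon
    coordinate.  Per 100 nm bin the dwell time of each trajectory is
    accumulated; per 1 µm bin a trajectory is flagged *slow* when its summed
    crossing time exceeds ``slow_threshold`` seconds, and the reported
    fraction pools passes in both directions.  Unvisited bins are NaN.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    xs = np.concatenate([np.asarray(x, dtype=float) for _, x in trajectories])
    lo = np.floor(xs.min() / bin_size) * bin_size
    hi = np.ceil(xs.max() / bin_size) * bin_size + bin_size
    edges = np.arange(lo, hi + 0.5 * bin_size, bin_size)
    n_bins = len(edges) - 1
    times = np.full((len(trajectories), n_bins), np.nan)
    for i, (t, x) in enumerate(trajectories):
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        dt = np.diff(t)
        dt = np.append(dt, dt[-1] if len(dt) else 0.0)
        idx = np.clip(((x - lo) / bin_size).astype(int), 0, n_bins - 1)
        dwell = np.bincount(idx, weights=dt, minlength=n_bins)
        visited = np.bincount(idx, minlength=n_bins) > 0
        times[i, visited] = dwell[visited]
    ratio = int(round(coarse_size / bin_size))
    n_coarse = int(np.ceil(n_bins / ratio))
    pad = n_coarse * ratio - n_bins
    padded = np.pad(times, ((0, 0), (0, pad)), constant_values=np.nan)
    coarse = np.nansum(padded.reshape(len(trajectories), n_coarse, ratio), axis=2)
    coarse_visited = ~np.all(np.isnan(padded.reshape(len(trajectories), n_coarse, ratio)), axis=2)
    flags = (coarse > slow_threshold) & coarse_visited
    visits = coarse_visited.sum(axis=0)
    with np.errstate(invalid="ignore"):
        slow_fraction = np.where(visits > 0, flags.sum(axis=0) / np.maximum(visits, 1), np.nan)
    coarse_edges = np.arange(lo, lo + (n_coarse + 0.5) * coarse_size, coarse_size)
    return CrossingProfile(
        bin_edges=edges,
        crossing_times=times,
        coarse_edges=coarse_edges,
        slow_fraction=slow_fraction,
        slow_flags=flags,
    )
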