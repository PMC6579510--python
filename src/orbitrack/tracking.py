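"""Fourier-sector localization and the closed-loop orbital tracker.

One orbit yields 16 sector photon counts per detection plane.  Localization
uses only the zero- and first-order Fourier coefficients of the
plane-summed sector series:

    phi    = atan2(b1, a1)
    Mod_xy = sqrt(a1^2 + b1^2) / a0
    dr     = r_orbit * f(Mod_xy)          (lateral displacement)
    Mod_z  = (I1 - I2) / (I1 + I2)
    dz     = plane_sep * g(Mod_z)         (axial displacement)

with f and g the tabulated scaling functions (:mod:`orbitrack.lut`).  The
feedback loop re-centers the orbit on the estimate after every illuminated
orbit, falls back to an Archimedean spiral search when the count rate drops
below threshold, and hands the accumulated galvo offset to the sample stage
(with a per-axis dead time) once it exceeds the long-range threshold, so the
sample-fixed coordinate stage + galvo stays continuous across recentering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lut import LUT, build_lut
from .motion import GroundTruthTrajectory
from .psf import Emitter, PSFModel, SectorCounts, sector_means

__all__ = [
    "NoSignal",
    "OrbitConfig",
    "TrackerState",
    "OrbitRecord",
    "RawTrajectory",
    "first_order_coeffs",
    "localize_xy",
    "localize_z",
    "feedback_step",
    "spiral_search",
    "long_range_recenter",
    "run_tracking",
]


class NoSignal(ValueError):
    """Raised when an orbit carries no photons at all (distinct from zero offset)."""


@dataclass(frozen=True)
class OrbitConfig:
    """Orbit geometry, timing and feedback thresholds.

    Dead times are the per-axis stage settle times during a long-range
    recentering event (no localization records are produced while waiting).
    ``dark_orbit_factor`` n means only every n-th orbit is illuminated; n = 2
    with a 5 ms orbit gives the 100 Hz effective sampling used in vivo.
    """

    orbit_radius: float = 150.0
    n_sectors: int = 16
    orbit_period: float = 0.005
    dark_orbit_factor: int = 2
    count_threshold: float = 50.0
    recenter_threshold: float = 10_000.0
    dead_time_x: float = 0.063
    dead_time_y: float = 0.035
    plane_separation: float = 1000.0
    spiral_max_radius: float = 5_000.0
    spiral_points_per_turn: int = 16

    def __post_init__(self) -> None:
        if self.n_sectors < 8 or self.n_sectors % 2:
            raise ValueError("n_sectors must be even and >= 8")
        if self.orbit_period <= 0:
            raise ValueError("orbit period must be positive")
        if self.dark_orbit_factor < 1:
            raise ValueError("dark_orbit_factor must be >= 1")
        if self.recenter_threshold <= 0:
            raise ValueError("recenter threshold must be positive")
        if self.orbit_radius <= 0:
            raise ValueError("orbit radius must be positive")

    @property
    def sample_interval(self) -> float:
        """Effective localization interval (s): orbit period x dark-orbit factor."""
        return self.orbit_period * self.dark_orbit_factor


@dataclass
class TrackerState:
    """Mutable state of the feedback loop (galvo + stage, both nm)."""

    galvo: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stage: np.ndarray = field(default_factory=lambda: np.zeros(3))
    searching: bool = False
    search_origin: np.ndarray | None = None
    search_index: int = 0
    dead_until: float = -np.inf
    lost: bool = False
    prev_galvo: np.ndarray | None = None

    @property
    def beam_center(self) -> np.ndarray:
        """Sample-fixed beam (orbit) center = stage + galvo."""
        return self.stage + self.galvo


@dataclass
class OrbitRecord:
    """One localization attempt of the feedback loop."""

    timestamp: float
    position: np.ndarray  # sample-fixed estimate, NaN when not tracked
    counts: float
    tracked: bool
    recenter_axis: str = ""
    clamped: bool = False


@dataclass
class RawTrajectory:
    """Time-ordered tracker output in sample-fixed coordinates."""

    times: np.ndarray
    positions: np.ndarray
    counts: np.ndarray
    tracked: np.ndarray
    recenter_axis: np.ndarray
    status: str = "ok"
    config: OrbitConfig | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = self.tracked & ~np.all(np.isfinite(self.positions), axis=1)
        if np.any(bad):
            raise ValueError("tracked records must have finite positions")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.times,
            "x_nm": self.positions[:, 0],
            "y_nm": self.positions[:, 1],
            "z_nm": self.positions[:, 2],
            "counts": self.counts,
            "tracked": self.tracked.astype(int),
            "recenter_axis": self.recenter_axis,
        })


def first_order_coeffs(counts: np.ndarray | SectorCounts) -> tuple[float, float, float]:
    """Zero- and first-order Fourier coefficients of the sector series.

    ``counts`` may be a :class:`SectorCounts` (planes are summed) or a 1D
    plane-summed array.  Sector k is attributed its midpoint angle
    ``2*pi*(k + 1/2)/n``.  Convention: a pattern ``C + A*cos(phi_k)`` returns
    ``(2C, A, 0)``; a pure sine returns ``b1 = A``.
    """
    if isinstance(counts, SectorCounts):
        c = counts.counts.sum(axis=1)
    else:
        c = np.asarray(counts, dtype=float)
    n = len(c)
    if n < 8:
        raise ValueError("need at least 8 sectors")
    if not np.any(c > 0):
        raise NoSignal("all sector counts are zero")
    f = np.fft.rfft(c)
    a0 = 2.0 * f[0].real / n
    s = (2.0 / n) * np.exp(-1j * np.pi / n) * f[1]  # midpoint-angle phase correction
    return float(a0), float(s.real), float(-s.imag)


def localize_xy(
    counts: np.ndarray | SectorCounts, lut_f: LUT, cfg: OrbitConfig
) -> tuple[float, float, bool]:
    """Lateral displacement (dx, dy) nm of the particle from the orbit center.

    Returns ``(dx, dy, clamped)``; ``clamped`` is True when the measured
    modulation exceeded the calibration range (particle near the orbit edge),
    in which case the displacement is clamped to the table maximum.
    """
    a0, a1, b1 = first_order_coeffs(counts)
    if a0 <= 0:
        raise NoSignal("non-positive mean intensity")
    mod = float(np.hypot(a1, b1)) / a0
    phi = float(np.arctan2(b1, a1))
    d_units, clamped = lut_f(mod)
    dr = cfg.orbit_radius * d_units
    return dr * np.cos(phi), dr * np.sin(phi), clamped


def localize_z(
    plane_counts: tuple[float, float] | SectorCounts, lut_g: LUT, cfg: OrbitConfig
) -> float:
    """Axial displacement dz nm from the two-plane intensity contrast.

    Positive dz points toward detection plane 1 (above the focal plane).
    """
    if isinstance(plane_counts, SectorCounts):
        i1 = float(plane_counts.counts[:, 0].sum())
        i2 = float(plane_counts.counts[:, 1].sum())
    else:
        i1, i2 = float(plane_counts[0]), float(plane_counts[1])
    if i1 + i2 <= 0:
        raise NoSignal("no photons in either detection plane")
    mod = (i1 - i2) / (i1 + i2)
    d_units, _ = lut_g(mod)
    return cfg.plane_separation * d_units


def spiral_search(state: TrackerState, cfg: OrbitConfig) -> np.ndarray:
    """Next probe center (galvo coordinates) of the Archimedean search spiral.

    The spiral winds around the last tracked galvo position with a pitch of
    one orbit radius per turn, advancing one angular step per orbit.  When
    the probe radius exceeds ``cfg.spiral_max_radius`` the particle is
    declared lost.
    """
    if not state.searching:
        raise ValueError("spiral_search requires search mode to be active")
    origin = state.search_origin if state.search_origin is not None else state.galvo[:2]
    state.search_index += 1
    theta = 2.0 * np.pi * state.search_index / cfg.spiral_points_per_turn
    radius = cfg.orbit_radius * theta / (2.0 * np.pi)  # pitch = r_orbit per turn
    if radius > cfg.spiral_max_radius:
        state.lost = True
        return state.galvo.copy()
    probe = state.galvo.copy()
    probe[0] = origin[0] + radius * np.cos(theta)
    probe[1] = origin[1] + radius * np.sin(theta)
    return probe


def long_range_recenter(state: TrackerState, cfg: OrbitConfig, t: float) -> str:
    """Hand the galvo offset to the stage when it exceeds the range threshold.

    Axes are handled independently: the stage absorbs the full galvo offset
    of the offending axis, the galvo is zeroed, and localization pauses for
    that axis's dead time.  Returns the axis string ("", "x", "y" or "xy").
    """
    axes = ""
    for axis, name, dead in ((0, "x", cfg.dead_time_x), (1, "y", cfg.dead_time_y)):
        if abs(state.galvo[axis]) > cfg.recenter_threshold:
            state.stage[axis] += state.galvo[axis]
            state.galvo[axis] = 0.0
            state.dead_until = max(state.dead_until, t + dead)
            axes += name
    return axes


def feedback_step(
    state: TrackerState,
    counts: SectorCounts,
    cfg: OrbitConfig,
    lut_f: LUT,
    lut_g: LUT,
) -> OrbitRecord:
    """Advance the feedback loop by one illuminated orbit.

    Above the count threshold the orbit center moves onto the localization
    estimate (taking effect on the next orbit) and a tracked record is
    emitted; below it the search spiral supplies the next probe center and
    an untracked record is emitted.  Long-range recentering is checked after
    every tracked update.
    """
    t = counts.timestamp
    if counts.total() >= cfg.count_threshold:
        dx, dy, clamped = localize_xy(counts, lut_f, cfg)
        dz = localize_z(counts, lut_g, cfg)
        est = np.array([dx, dy, dz])
        position = state.stage + state.galvo + est
        state.prev_galvo = state.galvo.copy()
        state.galvo = state.galvo + est
        state.searching = False
        state.search_origin = None
        state.search_index = 0
        axis = long_range_recenter(state, cfg, t)
        return OrbitRecord(t, position, counts.total(), True, axis, clamped)
    # below threshold: engage / continue the spiral search
    if not state.searching:
        state.searching = True
        state.search_origin = state.galvo[:2].copy()
        state.search_index = 0
    state.prev_galvo = state.galvo.copy()
    state.galvo = spiral_search(state, cfg)
    return OrbitRecord(t, np.full(3, np.nan), counts.total(), False, "")


def run_tracking(
    ground_truth,
    psf: PSFModel,
    cfg: OrbitConfig,
    rng: np.random.Generator | None,
    emitter: Emitter | None = None,
    duration: float | None = None,
    lut_f: LUT | None = None,
    lut_g: LUT | None = None,
    initial_offset: np.ndarray | tuple = (0.0, 0.0, 0.0),
) -> RawTrajectory:
    """Closed-loop tracking simulation against a ground-truth motion.

    ``ground_truth`` is a :class:`~orbitrack.motion.GroundTruthTrajectory`
    (its noise-free path is followed) or a callable ``t -> (x, y, z)`` nm.
    ``emitter`` supplies brightness/shape (position is overridden each
    orbit); ``rng=None`` runs the loop on noiseless photon counts, which is
    the configuration used for precision oracles.  The tracker starts with
    the orbit centered ``initial_offset`` nm away from the true position.
    """
    if isinstance(ground_truth, GroundTruthTrajectory):
        pos_at = ground_truth.position_at
        total = ground_truth.duration if duration is None else duration
    else:
        pos_at = ground_truth
        if duration is None:
            raise ValueError("duration is required for callable ground truth")
        total = duration
    if total < 1.0:
        raise ValueError("ground-truth duration must be at least 1 s")
    if emitter is None:
        emitter = Emitter(brightness=500.0)
    if lut_f is None:
        lut_f = build_lut(psf, cfg.orbit_radius, "lateral", cfg.n_sectors)
    if lut_g is None:
        lut_g = build_lut(psf, cfg.orbit_radius, "axial", cfg.n_sectors)

    state = TrackerState(galvo=np.asarray(pos_at(0.0), dtype=float) + np.asarray(initial_offset, dtype=float))
    records: list[OrbitRecord] = []
    n_orbits = int(total / cfg.orbit_period)
    n_illuminated = 0
    for k in range(n_orbits):
        t = k * cfg.orbit_period
        if t < state.dead_until:
            continue  # stage settling: no localization records
        if k % cfg.dark_orbit_factor:
            continue  # dark orbit: laser off, no counts
        true_pos = np.asarray(pos_at(t), dtype=float)
        brightness = emitter.brightness * np.exp(-emitter.bleach_rate * n_illuminated)
        n_illuminated += 1
        em = Emitter(
            position=true_pos,
            brightness=brightness,
            length=emitter.length,
            orientation=emitter.orientation,
            bleach_rate=emitter.bleach_rate,
        )
        sector_centers = None
        if cfg.dark_orbit_factor == 1 and state.prev_galvo is not None:
            # on-the-fly update: the first sector of this orbit still circles
            # the previous center (no settling gap between orbits)
            sector_centers = np.broadcast_to(state.beam_center, (cfg.n_sectors, 3)).copy()
            sector_centers[0] = state.stage + state.prev_galvo
        means = sector_means(
            psf, em, state.beam_center, cfg.orbit_radius, cfg.n_sectors, sector_centers
        )
        c = means if rng is None else rng.poisson(means).astype(float)
        counts = SectorCounts(c, timestamp=t, orbit_center=state.beam_center.copy())
        records.append(feedback_step(state, counts, cfg, lut_f, lut_g))
        if state.lost:
            break

    status = "lost" if state.lost else "ok"
    return RawTrajectory(
        times=np.array([r.timestamp for r in records]),
        positions=np.array([r.position for r in records]),
        counts=np.array([r.counts for r in records]),
        tracked=np.array([r.tracked for r in records]),
        recenter_axis=np.array([r.recenter_axis for r in records], dtype="<U2"),
        status=status,
        config=cfg,
    )
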