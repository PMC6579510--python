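"""Active-phase kinematics and fast/slow velocity classification.

Each contiguous active run of the segmentation becomes a motion phase with a
direction (sign of its net x displacement; anterograde = +x), a duration, a
lateral displacement and a mean velocity.  Phase velocities of the
trajectory's dominant direction form a two-component distribution — the fast
(kinesin/dynein-like, ~0.6-0.8 µm/s) and slow (~0.4 µm/s) transport states —
separated by a maximum-likelihood two-Gaussian fit; the classification
threshold is the midpoint of the two fitted centers.  Fast motion occurs in
only one direction per trajectory, so phases of the non-dominant direction
are all assigned the slow state.

Kinematics are computed on positions smoothed by a short moving average
(default 5 samples) to suppress tracker noise in the per-orbit displacement
histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .motion import STATES
from .segmentation import smooth_positions

__all__ = [
    "MotionPhase",
    "MixtureFit",
    "extract_phases",
    "fit_velocity_mixture",
    "classify_phases",
    "five_state_labels",
    "phase_table",
]


@dataclass
class MotionPhase:
    """One contiguous phase of directed transport."""

    start: float              # s
    end: float                # s
    start_index: int
    end_index: int            # exclusive
    direction: str            # "antero" | "retro"
    duration: float           # s
    xy_displacement: float    # µm, net lateral displacement
    velocity: float           # µm/s, xy_displacement / duration
    x_steps: np.ndarray = field(repr=False, default=None)  # per-sample dx, nm
    y_steps: np.ndarray = field(repr=False, default=None)  # per-sample dy, nm
    speed_class: str | None = None  # "fast" | "slow" after classification

    @property
    def state(self) -> str:
        if self.speed_class is None:
            raise ValueError("phase not yet classified into fast/slow")
        return f"{self.speed_class}_{self.direction}"


@dataclass
class MixtureFit:
    """Two-component Gaussian ML fit of phase velocities (µm/s)."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    weight1: float
    degenerate: bool

    @property
    def threshold(self) -> float:
        """Fast/slow class boundary: the mean of the two fitted centers."""
        return 0.5 * (self.mu1 + self.mu2)


def extract_phases(
    labels: np.ndarray,
    positions: np.ndarray,
    times: np.ndarray,
    smooth: int = 5,
) -> list[MotionPhase]:
    """Motion phases from a boolean active mask and the trajectory.

    Direction is the sign of the phase's net x displacement; velocity is the
    net lateral displacement over the duration.  Per-sample x/y steps of the
    smoothed positions are retained for the orbit-displacement histograms.
    """
    labels = np.asarray(labels, dtype=bool)
    positions = np.asarray(positions, dtype=float)
    if len(labels) != len(positions):
        raise ValueError("labels must align with the trajectory")
    sm = smooth_positions(positions, smooth)
    phases: list[MotionPhase] = []
    edges = np.flatnonzero(np.diff(labels.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(labels)]])
    for s, e in zip(starts, ends):
        if not labels[s]:
            continue
        dx = sm[e - 1, 0] - sm[s, 0]
        dy = sm[e - 1, 1] - sm[s, 1]
        duration = float(times[e - 1] - times[s])
        if duration <= 0:
            continue
        disp_um = float(np.hypot(dx, dy)) / 1000.0
        phases.append(MotionPhase(
            start=float(times[s]),
            end=float(times[e - 1]),
            start_index=int(s),
            end_index=int(e),
            direction="antero" if dx >= 0 else "retro",
            duration=duration,
            xy_displacement=disp_um,
            velocity=disp_um / duration,
            x_steps=np.diff(sm[s:e, 0]),
            y_steps=np.diff(sm[s:e, 1]),
        ))
    return phases


def fit_velocity_mixture(
    velocities: np.ndarray,
    rng: np.random.Generator | None = None,
    n_init: int = 10,
) -> MixtureFit:
    """Maximum-likelihood two-Gaussian fit of a velocity sample.

    Components are ordered mu1 < mu2.  The fit is declared degenerate (single
    mode) when the centers are closer than half the larger component width;
    callers then assign every phase to the slow state.
    """
    v = np.asarray(velocities, dtype=float).reshape(-1, 1)
    if len(v) < 10:
        warnings.warn("fewer than 10 phases: velocity mixture fit is degenerate")
        m, s = float(v.mean()), float(v.std())
        return MixtureFit(m, s, m, s, 1.0, True)
    seed = None if rng is None else int(rng.integers(2**31 - 1))
    gm = GaussianMixture(
        n_components=2, n_init=n_init, init_params="kmeans", random_state=seed
    ).fit(v)
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    ws = gm.weights_.ravel()
    order = np.argsort(mus)
    mu1, mu2 = mus[order]
    s1, s2 = sds[order]
    w1 = ws[order][0]
    # single-mode data: the fitted two-component density has no valley
    # between the centers (a 2-component fit of one Gaussian yields
    # overlapping halves whose sum is unimodal)
    def density(x):
        return (w1 / s1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
                + (1 - w1) / s2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))

    dip = density(0.5 * (mu1 + mu2)) / min(density(mu1), density(mu2))
    degenerate = dip >= 0.9
    if degenerate:
        warnings.warn("velocity mixture is single-mode; all phases assigned slow")
    return MixtureFit(float(mu1), float(s1), float(mu2), float(s2), float(w1), degenerate)


def classify_phases(
    phases: list[MotionPhase],
    rng: np.random.Generator | None = None,
) -> MixtureFit | None:
    """Assign fast/slow speed classes to the phases of one trajectory (in place).

    The dominant direction (larger summed displacement) carries the fast
    state; its velocity histogram is fitted with the two-Gaussian mixture and
    phases above the center midpoint become fast.  All phases of the other
    direction, and every phase when the fit is degenerate, become slow.
    Returns the mixture fit (None when there are no phases).
    """
    if not phases:
        return None
    disp = {"antero": 0.0, "retro": 0.0}
    for p in phases:
        disp[p.direction] += p.xy_displacement
    dominant = max(disp, key=disp.get)
    vel = np.array([p.velocity for p in phases if p.direction == dominant])
    fit = fit_velocity_mixture(vel, rng)
    for p in phases:
        if p.direction != dominant or fit.degenerate:
            p.speed_class = "slow"
        else:
            p.speed_class = "fast" if p.velocity > fit.threshold else "slow"
    return fit


def five_state_labels(labels: np.ndarray, phases: list[MotionPhase]) -> np.ndarray:
    """Per-sample five-state labels from the binary mask and classified phases."""
    out = np.full(len(labels), "stationary", dtype="<U12")
    for p in phases:
        out[p.start_index:p.end_index] = p.state
    return out


def phase_table(phases: list[MotionPhase]) -> pd.DataFrame:
    """Tabular view of a phase list (one row per phase)."""
    rows = []
    for p in phases:
        rows.append({
            "start_s": p.start,
            "end_s": p.end,
            "direction": p.direction,
            "speed_class": p.speed_class or "",
            "state": p.state if p.speed_class else "",
            "duration_s": p.duration,
            "xy_displacement_um": p.xy_displacement,
            "velocity_um_s": p.velocity,
        })
    df = pd.DataFrame(rows, columns=[
        "start_s", "end_s", "direction", "speed_class", "state",
        "duration_s", "xy_displacement_um", "velocity_um_s",
    ])
    return df


def _check_states(states: np.ndarray) -> None:
    bad = set(np.unique(states)) - set(STATES)
    if bad:
        raise ValueError(f"unknown state labels: {sorted(bad)}")
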