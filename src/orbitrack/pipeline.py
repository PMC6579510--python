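"""Convenience wrappers binding segmentation, classification and statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SegmentationConfig
from .phases import (MixtureFit, MotionPhase, classify_phases, extract_phases,
                     five_state_labels)
from .segmentation import CorrelationCarpet, segment_trajectory

__all__ = ["TrajectoryAnalysis", "analyze_trajectory", "segmentation_accuracy"]


@dataclass
class TrajectoryAnalysis:
    """Bundled per-trajectory results of the motion-state pipeline."""

    labels: np.ndarray                    # five-state per-sample labels
    active: np.ndarray                    # boolean active mask
    phases: list[MotionPhase] = field(default_factory=list)
    mixture: MixtureFit | None = None
    carpet: CorrelationCarpet | None = None

    @property
    def stationary_x_steps(self) -> np.ndarray:
        """Per-sample x displacements (nm) of the stationary samples."""
        return self._stationary_steps


def analyze_trajectory(
    times: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    cfg: SegmentationConfig | None = None,
) -> TrajectoryAnalysis:
    """Segment one trajectory into five motion states.

    Runs the angle-autocorrelation segmentation, extracts active phases,
    classifies them fast/slow via the velocity-mixture fit, and returns the
    per-sample five-state labels alongside the intermediate objects.
    """
    cfg = cfg or SegmentationConfig()
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    dt = float(np.median(np.diff(times)))
    active, carpet = segment_trajectory(
        positions, dt, rng,
        window=cfg.window, tau_interval=cfg.tau_interval, mode=cfg.mode,
        smooth=cfg.smooth, n_shuffles=cfg.n_shuffles,
        min_active_duration=cfg.min_active_duration,
    )
    phases = extract_phases(active, positions, times, smooth=cfg.smooth)
    mixture = classify_phases(phases, rng)
    labels = five_state_labels(active, phases)
    result = TrajectoryAnalysis(
        labels=labels, active=active, phases=phases, mixture=mixture, carpet=carpet
    )
    from .segmentation import smooth_positions

    sm = smooth_positions(positions, cfg.smooth)
    steps = np.diff(sm[:, 0])
    result._stationary_steps = steps[~active[:-1]]
    return result


def segmentation_accuracy(
    rng: np.random.Generator,
    n_trajectories: int = 20,
    duration: float = 60.0,
    cfg: SegmentationConfig | None = None,
    params=None,
) -> tuple[float, int]:
    """Fraction of samples given the correct active/stationary label.

    Generates ``n_trajectories`` synthetic trajectories under the
    segmentation-validation conditions (see
    :func:`~orbitrack.motion.validation_state_params`), segments each, and
    scores the per-sample binary labels against the generating ground truth.
    Returns ``(accuracy, n_samples)``.
    """
    from .motion import generate_state_trajectory, validation_state_params
    from .segmentation import segment_trajectory

    cfg = cfg or SegmentationConfig()
    params = params or validation_state_params()
    correct = total = 0
    for _ in range(n_trajectories):
        gt = generate_state_trajectory(params, duration, rng)
        labels, _ = segment_trajectory(
            gt.positions, params.sample_interval, rng,
            window=cfg.window, tau_interval=cfg.tau_interval, mode=cfg.mode,
            smooth=cfg.smooth, n_shuffles=cfg.n_shuffles,
            min_active_duration=cfg.min_active_duration,
        )
        correct += int((labels == (gt.states != "stationary")).sum())
        total += gt.n_samples
    return correct / total, total
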