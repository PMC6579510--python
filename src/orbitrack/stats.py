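"""Population statistics of motion states and state transitions.

Summary values follow the 10-subset procedure: each per-state sample set is
randomly partitioned into 10 equal-size subsets, the stated model is fitted
per subset — a Gaussian for velocities, a single-exponential decay for
durations and displacements — and the reported value is the mean ± std of
the fitted parameter across subsets, which also provides the replicates for
two-sided t-tests between states.  Per-orbit x-displacement histograms are
fitted by a single Gaussian directly.

Transitions are ordered pairs of consecutive active phases; the stationary
gap between them is the pause, classed by its flanking speed states
(fast-fast, fast-slow/slow-fast, slow-slow) and fitted with a
mono-exponential decay per class.  Direction-change probabilities are
reported separately for pauses shorter and longer than 20 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phases import MotionPhase

__all__ = [
    "subset_fit",
    "state_statistics",
    "compare_states",
    "TransitionTable",
    "transition_analysis",
]

_ACTIVE = ("fast_antero", "slow_antero", "fast_retro", "slow_retro")


def subset_fit(
    values: np.ndarray,
    model: str,
    rng: np.random.Generator,
    n_subsets: int = 10,
) -> tuple[float, float, np.ndarray]:
    """Fit ``model`` on 10 random equal-size subsets of ``values``.

    ``model`` is ``"gaussian"`` (fitted parameter: the center) or
    ``"exponential"`` (fitted parameter: the ML decay constant, i.e. the
    subset mean).  Returns ``(mean, std, fits)`` across subsets; the fits
    array provides replicates for t-tests.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2 * n_subsets:
        warnings.warn("too few samples for subset fitting; reporting raw mean/std")
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        return float(values.mean()), sd, values.copy()
    perm = rng.permutation(values)
    usable = (len(perm) // n_subsets) * n_subsets
    subsets = perm[:usable].reshape(n_subsets, -1)
    if model == "gaussian":
        fits = subsets.mean(axis=1)  # ML center of a Gaussian
    elif model == "exponential":
        fits = subsets.mean(axis=1)  # ML decay constant of Exp(tau)
    else:
        raise ValueError("model must be 'gaussian' or 'exponential'")
    return float(fits.mean()), float(fits.std(ddof=1)), fits


def state_statistics(
    phases: list[MotionPhase],
    rng: np.random.Generator,
    stationary_x_steps: np.ndarray | None = None,
    n_subsets: int = 10,
) -> pd.DataFrame:
    """Per-state summary of duration, displacement, velocity and orbit displacement.

    One row per (state, quantity): the 10-subset estimate ± std, the model
    used, the sample size, and the distribution mean ± std of the raw
    values.  Orbit displacements (per-sample x steps, nm) are fitted by a
    single Gaussian directly, including the pooled stationary samples when
    supplied.
    """
    quantities = {
        "duration_s": ("exponential", lambda p: p.duration),
        "xy_displacement_um": ("exponential", lambda p: p.xy_displacement),
        "xy_velocity_um_s": ("gaussian", lambda p: p.velocity),
    }
    rows = []
    for state in _ACTIVE:
        sel = [p for p in phases if p.speed_class and p.state == state]
        if not sel:
            continue
        for qty, (model, get) in quantities.items():
            vals = np.array([get(p) for p in sel])
            est, sd, _ = subset_fit(vals, model, rng, n_subsets)
            rows.append({
                "state": state, "quantity": qty, "model": model,
                "estimate": est, "estimate_sd": sd, "n": len(vals),
                "raw_mean": float(vals.mean()),
                "raw_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            })
        steps = np.concatenate([p.x_steps for p in sel]) if sel else np.array([])
        if len(steps):
            mu, sd = sps.norm.fit(steps)
            rows.append({
                "state": state, "quantity": "x_orbit_displacement_nm",
                "model": "gaussian_direct", "estimate": float(mu),
                "estimate_sd": float(sd), "n": len(steps),
                "raw_mean": float(steps.mean()), "raw_sd": float(steps.std(ddof=1)),
            })
    if stationary_x_steps is not None and len(stationary_x_steps):
        mu, sd = sps.norm.fit(np.asarray(stationary_x_steps, dtype=float))
        rows.append({
            "state": "stationary", "quantity": "x_orbit_displacement_nm",
            "model": "gaussian_direct", "estimate": float(mu),
            "estimate_sd": float(sd), "n": len(stationary_x_steps),
            "raw_mean": float(np.mean(stationary_x_steps)),
            "raw_sd": float(np.std(stationary_x_steps, ddof=1)),
        })
    return pd.DataFrame(rows)


def compare_states(fits_a: np.ndarray, fits_b: np.ndarray) -> float:
    """Two-sided t-test p-value between two sets of subset fits."""
    return float(sps.ttest_ind(fits_a, fits_b).pvalue)


@dataclass
class TransitionTable:
    """Counts and pause statistics of consecutive active-phase pairs."""

    counts: pd.DataFrame                 # 4x4 from-state x to-state
    pauses: dict = field(default_factory=dict)           # class -> durations (s)
    decay_constants: dict = field(default_factory=dict)  # class -> ML tau (s)
    direction_change: dict = field(default_factory=dict) # "short"/"long" -> (p, n)

    @property
    def probabilities(self) -> pd.DataFrame:
        """Row-normalized transition probabilities (rows with no exits are NaN)."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0)


def _pause_class(a: MotionPhase, b: MotionPhase) -> str:
    fast_a = a.speed_class == "fast"
    fast_b = b.speed_class == "fast"
    if fast_a and fast_b:
        return "fast-fast"
    if fast_a or fast_b:
        return "fast-slow"
    return "slow-slow"


def transition_analysis(
    phases: list[MotionPhase],
    long_pause: float = 20.0,
) -> TransitionTable:
    """Transition counts, pause-duration decays and direction-change rates.

    ``phases`` must be classified and time-ordered (one trajectory, or the
    concatenation of per-trajectory lists — pairs are only formed within a
    contiguous run of increasing start times).  A trajectory-terminal
    stationary stretch is not a pause.
    """
    counts = pd.DataFrame(0, index=list(_ACTIVE), columns=list(_ACTIVE), dtype=int)
    pauses: dict[str, list] = {"fast-fast": [], "fast-slow": [], "slow-slow": []}
    changes = {"short": [0, 0], "long": [0, 0]}  # [direction changes, total]
    for a, b in zip(phases[:-1], phases[1:]):
        if b.start < a.end:  # new trajectory began
            continue
        if a.speed_class is None or b.speed_class is None:
            raise ValueError("phases must be classified before transition analysis")
        counts.loc[a.state, b.state] += 1
        gap = b.start - a.end
        if gap > 0:
            pauses[_pause_class(a, b)].append(gap)
            bucket = "long" if gap >= long_pause else "short"
            changes[bucket][1] += 1
            changes[bucket][0] += a.direction != b.direction
    decay = {
        cls: (float(np.mean(v)) if v else np.nan) for cls, v in pauses.items()
    }
    direction_change = {
        k: ((c / n if n else np.nan), n) for k, (c, n) in changes.items()
    }
    return TransitionTable(
        counts=counts,
        pauses={k: np.array(v) for k, v in pauses.items()},
        decay_constants=decay,
        direction_change=direction_change,
    )
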