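"""Trajectory visual diagnostics: kymographs and heartbeat artifact QC.

A kymograph projects the trajectory onto the axon axis (x) against time,
optionally colored by motion state and overlaid with the positions of
stationary organelles.  The heartbeat check inspects the power spectrum of
the component perpendicular to the axon axis: in larvae mounted near blood
vessels the pulse imprints a 1-4 Hz lateral oscillation on the trajectory;
affected recordings are flagged and discarded rather than analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["kymograph", "plot_kymograph", "HeartbeatReport", "qc_heartbeat"]

_STATE_COLORS = {
    "fast_antero": "tab:green",
    "slow_antero": "gold",
    "fast_retro": "tab:blue",
    "slow_retro": "tab:orange",
    "stationary": "tab:red",
}


def kymograph(
    times: np.ndarray,
    positions: np.ndarray,
    states: np.ndarray | None = None,
) -> pd.DataFrame:
    """Position-along-axon vs time projection, one row per sample.

    Columns: ``t_s``, ``x_um`` and (when labels are supplied) ``state``.
    Constant-velocity phases appear as straight lines whose slope is the
    phase velocity; stationary phases as horizontal bands.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(times) == 0:
        raise ValueError("empty trajectory")
    out = pd.DataFrame({"t_s": times, "x_um": positions[:, 0] / 1000.0})
    if states is not None:
        out["state"] = np.asarray(states)
    return out


def plot_kymograph(kymo: pd.DataFrame, path=None, object_intervals=None):
    """Render a kymograph colored by state; optionally save to ``path``.

    ``object_intervals`` is an iterable of (x_lo_um, x_hi_um) bands marking
    stationary organelles.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if "state" in kymo:
        for state, grp in kymo.groupby("state"):
            ax.plot(grp["t_s"], grp["x_um"], ".", ms=1.5,
                    color=_STATE_COLORS.get(state, "gray"), label=state)
        ax.legend(markerscale=8, fontsize=7)
    else:
        ax.plot(kymo["t_s"], kymo["x_um"], "k.", ms=1.5)
    if object_intervals is not None:
        for lo, hi in object_intervals:
            ax.axhspan(lo, hi, color="0.85", zorder=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position along axon (µm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass
class HeartbeatReport:
    """Outcome of the perpendicular-oscillation spectral check."""

    flagged: bool
    peak_frequency: float   # Hz
    peak_amplitude: float   # nm
    band: tuple


def qc_heartbeat(
    times: np.ndarray,
    positions: np.ndarray,
    band: tuple = (1.0, 4.0),
    amplitude_threshold: float = 20.0,
) -> HeartbeatReport:
    """Flag trajectories carrying a periodic lateral-perpendicular artifact.

    The y component (perpendicular to the axon axis; axial motion is not
    inspected) is linearly detrended and its amplitude spectrum computed.
    The trajectory is flagged when the dominant spectral peak inside ``band``
    (Hz) exceeds ``amplitude_threshold`` nm.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if times[-1] - times[0] < 10.0:
        raise ValueError("heartbeat QC needs at least 10 s of data")
    fs = 1.0 / np.median(np.diff(times))
    y = signal.detrend(positions[:, 1])
    freqs, power = signal.periodogram(y, fs, scaling="spectrum")
    amplitude = np.sqrt(2.0 * power)  # one-sided spectrum -> sine amplitude
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        return HeartbeatReport(False, np.nan, 0.0, tuple(band))
    i = np.argmax(amplitude[sel])
    peak_f = float(freqs[sel][i])
    peak_a = float(amplitude[sel][i])
    return HeartbeatReport(peak_a > amplitude_threshold, peak_f, peak_a, tuple(band))
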