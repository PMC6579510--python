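"""Calibration lookup tables mapping intensity modulation to displacement.

The lateral modulation Mod(xy) = sqrt(a1^2 + b1^2)/a0 of the orbit intensity
and the axial plane contrast Mod(z) = (I1 - I2)/(I1 + I2) are dimensionless
observables; the scaling functions f(r) and g(z) that convert them into
physical displacement are not analytic for a finite orbit radius and are
therefore tabulated from noiseless simulations of the detection model, in
units of the orbit radius (lateral) and of the plane separation (axial).
Retrieval is a binary search over the strictly monotone modulation grid with
linear interpolation between nodes, mirroring the real-time implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psf import Emitter, PSFModel, sector_means

__all__ = ["LUT", "build_lut"]


@dataclass
class LUT:
    """Monotone modulation → displacement table for one axis.

    ``displacements`` are stored in units of the orbit radius (lateral) or
    the plane separation (axial), so a table is reusable across geometries
    with the same dimensionless shape.
    """

    axis: str  # "lateral" | "axial"
    modulations: np.ndarray
    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.modulations = np.asarray(self.modulations, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.axis not in ("lateral", "axial"):
            raise ValueError("axis must be 'lateral' or 'axial'")
        if self.modulations.shape != self.displacements.shape:
            raise ValueError("grids must have equal length")
        dm = np.diff(self.modulations)
        if np.any(dm <= 0):
            i = int(np.argmax(dm <= 0))
            raise ValueError(f"modulation grid not strictly increasing at index {i}")

    @property
    def mod_max(self) -> float:
        return float(self.modulations[-1])

    @property
    def mod_min(self) -> float:
        return float(self.modulations[0])

    def __call__(self, mod: float) -> tuple[float, bool]:
        """Displacement (table units) for a measured modulation.

        Binary search + linear interpolation.  Out-of-range modulations are
        clamped to the table edge; the second return value reports whether
        clamping occurred (particle near the orbit edge).
        """
        m = self.modulations
        if mod <= m[0]:
            return float(self.displacements[0]), mod < m[0]
        if mod >= m[-1]:
            return float(self.displacements[-1]), mod > m[-1]
        i = int(np.searchsorted(m, mod)) - 1
        f = (mod - m[i]) / (m[i + 1] - m[i])
        d = self.displacements[i] + f * (self.displacements[i + 1] - self.displacements[i])
        return float(d), False


def build_lut(
    psf: PSFModel,
    orbit_radius: float,
    axis: str,
    n_sectors: int = 16,
    n_grid: int = 256,
) -> LUT:
    """Tabulate modulation vs displacement from noiseless orbit simulations.

    Lateral: a point emitter is stepped from 0 to 1.5 orbit radii along +x
    and Mod(xy) recorded.  Axial: the emitter is stepped over ±0.75 plane
    separations and Mod(z) recorded.  A non-monotone modulation curve (a
    PSF/orbit combination with no unique inverse) raises with the first
    offending grid point.
    """
    from .tracking import first_order_coeffs  # local import to avoid a cycle

    if not np.isfinite(orbit_radius) or orbit_radius <= 0:
        raise ValueError("orbit radius must be positive and finite")
    if axis == "lateral":
        disp = np.linspace(0.0, 1.5 * orbit_radius, n_grid)
        mods = np.empty(n_grid)
        for i, d in enumerate(disp):
            em = Emitter(position=np.array([d, 0.0, 0.0]), brightness=1.0)
            counts = sector_means(psf, em, np.zeros(3), orbit_radius, n_sectors)
            a0, a1, b1 = first_order_coeffs(counts.sum(axis=1))
            mods[i] = np.hypot(a1, b1) / a0
        mods[0] = 0.0  # exact by symmetry; quadrature noise is ~1e-17
        units = orbit_radius
    elif axis == "axial":
        half = 0.75 * psf.plane_separation
        disp = np.linspace(-half, half, n_grid)
        mods = np.empty(n_grid)
        for i, d in enumerate(disp):
            em = Emitter(position=np.array([0.0, 0.0, d]), brightness=1.0)
            counts = sector_means(psf, em, np.zeros(3), orbit_radius, n_sectors)
            i1, i2 = counts[:, 0].sum(), counts[:, 1].sum()
            mods[i] = (i1 - i2) / (i1 + i2)
        units = psf.plane_separation
    else:
        raise ValueError("axis must be 'lateral' or 'axial'")

    dm = np.diff(mods)
    if np.any(dm <= 0):
        i = int(np.argmax(dm <= 0))
        raise ValueError(
            f"modulation curve not strictly monotone at displacement {disp[i]:.1f} nm "
            "(bad PSF/orbit combination)"
        )
    return LUT(axis=axis, modulations=mods, displacements=disp / units)
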