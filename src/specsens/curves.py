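"""Spectral curves: a wavelength grid with associated values.

`SpectralCurve` is the common container for measured sensitivities, model
absorptance spectra and pre-receptor transmittance curves. Wavelengths are in
nanometres and must be strictly increasing; values are dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import CurveError, DegenerateModelError


@dataclass(frozen=True, eq=False)
class SpectralCurve:
    """An immutable (wavelength, value) pair of equal-length 1-D arrays."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise CurveError("wavelengths and values must be 1-D arrays")
        if wl.size != vals.size:
            raise CurveError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size == 0:
            raise CurveError("empty curve")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise CurveError("curve contains non-finite entries")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise CurveError("wavelengths must be strictly increasing")
        wl.flags.writeable = False
        vals.flags.writeable = False
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.wavelengths.size)

    def interp(self, grid: np.ndarray, warn_extrapolate: bool = True) -> "SpectralCurve":
        """Linearly interpolate onto ``grid``, clamping to endpoint values.

        Points outside the curve's range take the nearest endpoint value;
        a warning is issued because clamped extrapolation is a modelling
        assumption, not data.
        """
        grid = np.asarray(grid, dtype=float)
        if warn_extrapolate and (
            grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9
        ):
            warnings.warn(
                f"grid [{grid[0]:.1f}, {grid[-1]:.1f}] nm extends beyond curve "
                f"range [{self.wavelengths[0]:.1f}, {self.wavelengths[-1]:.1f}] nm; "
                "clamping to endpoint values",
                stacklevel=2,
            )
        return SpectralCurve(grid, np.interp(grid, self.wavelengths, self.values))

    def peak_normalized(self) -> "SpectralCurve":
        """Scale so the maximum value is exactly 1."""
        peak = float(np.max(self.values))
        if peak <= 0.0:
            raise DegenerateModelError("cannot peak-normalize a non-positive curve")
        return SpectralCurve(self.wavelengths, self.values / peak)

    def argmax_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.values))])
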