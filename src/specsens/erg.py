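"""Reading, converting, binning and averaging spectral sensitivity data.

Extracellular ERG spectral sensitivities are published either as relative
sensitivity (peak 1) or as log10 sensitivity. They are converted to relative
units, binned onto a regular wavelength grid (20 nm by default in this
package's workflows) and, when several eye regions were recorded, averaged
into a single whole-eye curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SpectralCurve
from .exceptions import CurveError, CurveParseError

CSV_COLUMNS = ("wavelength_nm", "value")


@dataclass(frozen=True, eq=False)
class RawSensitivity:
    """As-published sensitivity values with their scale and region label."""

    wavelengths: np.ndarray
    values: np.ndarray
    scale: str = "relative"  # "relative" or "log10"
    region_label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise CurveError("wavelengths and values must be matching 1-D arrays")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise CurveError("raw sensitivity contains non-finite entries")
        if self.scale not in ("relative", "log10"):
            raise CurveError(f"unknown sensitivity scale {self.scale!r}")
        if self.scale == "relative" and np.any(vals < 0):
            raise CurveError("relative sensitivities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)


def to_relative(raw: RawSensitivity) -> SpectralCurve:
    """Convert to relative sensitivity with peak 1.

    log10 input: relative = 10^(value − max value). Relative input is
    peak-normalized (divided by its maximum).
    """
    if raw.scale == "log10":
        values = 10.0 ** (raw.values - np.max(raw.values))
    else:
        peak = float(np.max(raw.values))
        if peak <= 0:
            raise CurveError("relative sensitivity has non-positive maximum")
        values = raw.values / peak
    order = np.argsort(raw.wavelengths)
    return SpectralCurve(raw.wavelengths[order], values[order])


def bin_curve(
    curve: SpectralCurve, interval_nm: float, wavelength_range: tuple[float, float]
) -> SpectralCurve:
    """Average data points into regular bins centred on a grid.

    Bin centres run lo, lo+interval, ..., hi (endpoints inclusive), each bin
    covering centre ± interval/2 with the right edge open. Points outside
    [lo − interval/2, hi + interval/2) are dropped. Empty bins are filled by
    linear interpolation between neighbouring bins and flagged by warning.
    """
    lo, hi = (float(x) for x in wavelength_range)
    interval = float(interval_nm)
    if interval <= 0 or hi <= lo:
        raise CurveError(f"invalid binning range {wavelength_range} @ {interval} nm")
    n_steps = (hi - lo) / interval
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise CurveError(
            f"interval {interval} nm does not divide the range [{lo}, {hi}] nm"
        )
    centers = lo + interval * np.arange(int(round(n_steps)) + 1)

    idx = np.floor((curve.wavelengths - (lo - interval / 2.0)) / interval).astype(int)
    keep = (idx >= 0) & (idx < centers.size)
    sums = np.bincount(idx[keep], weights=curve.values[keep], minlength=centers.size)
    counts = np.bincount(idx[keep], minlength=centers.size)

    filled = counts > 0
    values = np.full(centers.size, np.nan)
    values[filled] = sums[filled] / counts[filled]
    if not np.any(filled):
        raise CurveError("no data points fall inside the binning range")
    if not np.all(filled):
        empty = centers[~filled]
        warnings.warn(
            f"{empty.size} empty bin(s) at {empty.tolist()} nm filled by linear "
            "interpolation",
            stacklevel=2,
        )
        values[~filled] = np.interp(centers[~filled], centers[filled], values[filled])
    return SpectralCurve(centers, values)


def average_regions(curves: list[SpectralCurve]) -> SpectralCurve:
    """Unweighted pointwise mean of same-grid region curves, peak-normalized."""
    if not curves:
        raise CurveError("no curves to average")
    grid = curves[0].wavelengths
    for c in curves[1:]:
        if c.n != curves[0].n or not np.allclose(c.wavelengths, grid, atol=1e-9):
            raise CurveError("region curves are not on an identical binned grid")
    mean = np.mean([c.values for c in curves], axis=0)
    return SpectralCurve(grid, mean).peak_normalized()


def read_curve_csv(path, region: str | None = None) -> SpectralCurve:
    """Read a two-column CSV (``wavelength_nm,value``) as a SpectralCurve.

    Files with a ``region`` column holding several regions require ``region=``
    to pick one (or use :func:`read_region_curves`).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CurveParseError(
            f"{path}: missing required column(s) {missing}; header must contain "
            f"{','.join(CSV_COLUMNS)}"
        )
    if "region" in df.columns:
        regions = df["region"].unique().tolist()
        if region is None:
            if len(regions) > 1:
                raise CurveParseError(
                    f"{path}: multiple regions {regions}; pass region= or use "
                    "read_region_curves()"
                )
            region = regions[0]
        df = df[df["region"] == region]
        if df.empty:
            raise CurveParseError(f"{path}: no rows for region {region!r}")
    return _frame_to_curve(df, path)


def read_region_curves(path) -> dict[str, SpectralCurve]:
    """Read a multi-region CSV into a dict of region label → curve."""
    df = pd.read_csv(path)
    if "region" not in df.columns:
        return {"": read_curve_csv(path)}
    return {
        str(label): _frame_to_curve(group, path)
        for label, group in df.groupby("region", sort=False)
    }


def _frame_to_curve(df: pd.DataFrame, path) -> SpectralCurve:
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    vals = df["value"].to_numpy(dtype=float)
    diffs = np.diff(wl)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        line = int(df.index[bad[0] + 1]) + 2
        kind = "duplicate" if diffs[bad[0]] == 0 else "non-monotone"
        raise CurveParseError(f"{path}: {kind} wavelength at line {line}")
    return SpectralCurve(wl, vals)


def write_curve_csv(curve: SpectralCurve, path) -> None:
    """Write a curve as ``wavelength_nm,value`` CSV (round-trips to ~1e-12)."""
    pd.DataFrame(
        {"wavelength_nm": curve.wavelengths, "value": curve.values}
    ).to_csv(path, index=False, float_format="%.12g")
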