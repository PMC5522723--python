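"""Visual pigment absorbance templates ("nomograms").

Rhodopsin absorbance spectra are well described by universal template curves
parameterized only by the wavelength of peak absorbance, λmax. Two widely
used A1-chromophore template families are implemented:

* **SSH** — a modified log-normal: the absorbance band is
  ``exp(-a x² (1 + b x + c x²))`` with ``x = log10(λ/λmax)``. A single peak
  of exactly 1 at λmax; the long-wavelength limb is the steeper one.
* **GFKRD** — a rational-exponential alpha band in the normalized frequency
  variable ``x = λmax/λ``:
  ``1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)``, where the
  coefficient ``a`` itself depends weakly on λmax.

The secondary UV ("beta") band is modelled with the GFKRD-family Gaussian
whose position and width scale linearly with λmax; its amplitude is relative
to an alpha peak of 1. Combined alpha+beta curves are renormalized to peak 1
so that a peak absorption coefficient k multiplying the template keeps its
meaning of absorbance per micrometre at the most absorbed wavelength.

All functions are vectorized over an arbitrary strictly-increasing grid; no
interpolation tables are involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import UnsupportedTemplateError, CurveError

FAMILIES = ("SSH", "GFKRD")

# Template coefficients, transcribed from the standard template literature.
# SSH alpha band: exp(-a x^2 (1 + b x + c x^2)), x = log10(lambda/lambda_max),
# with c tied to b as c = 3 b^2 / 8.
SSH_ALPHA = {"a": 380.0, "b": 6.09, "c": 3.0 * 6.09**2 / 8.0}

# GFKRD A1 alpha band: 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D),
# x = lambda_max/lambda; a = a0 + a1 * exp(-(lambda_max - 300)^2 / 11940).
GFKRD_ALPHA = {
    "A": 69.7,
    "B": 28.0,
    "C": -14.9,
    "D": 0.674,
    "b": 0.922,
    "c": 1.104,
    "a0": 0.8795,
    "a1": 0.0459,
    "a2": 300.0,
    "a3": 11940.0,
}

# GFKRD beta band: A_beta * exp(-((lambda - lm)/bw)^2) with
# lm = 189 + 0.315 lambda_max and bw = -40.5 + 0.195 lambda_max.
GFKRD_BETA = {"amplitude": 0.26, "lm0": 189.0, "lm1": 0.315, "bw0": -40.5, "bw1": 0.195}

# Range of lambda_max over which the template fits were calibrated, and the
# wavelength range over which evaluation is considered trustworthy. Outside
# these the functions still evaluate (they are analytic) but warn.
LAMBDA_MAX_CALIBRATED = (330.0, 620.0)
GRID_TRUSTED = (250.0, 800.0)


@dataclass(frozen=True)
class PigmentSpec:
    """One visual pigment: template family, λmax (nm), optional beta band."""

    family: str
    lambda_max: float
    include_beta: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UnsupportedTemplateError(
                f"unknown template family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (300.0 <= self.lambda_max <= 700.0):
            raise CurveError(
                f"lambda_max {self.lambda_max} nm outside the supported "
                "range [300, 700] nm"
            )


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise CurveError("wavelength grid must be a non-empty 1-D array")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise CurveError("wavelength grid must be strictly increasing")
    if wl[0] < GRID_TRUSTED[0] or wl[-1] > GRID_TRUSTED[1]:
        warnings.warn(
            f"grid extends outside the template validity range {GRID_TRUSTED} nm; "
            "values are extrapolations of the analytic form",
            stacklevel=3,
        )
    return wl


def _warn_lambda_max(lambda_max: float) -> None:
    lo, hi = LAMBDA_MAX_CALIBRATED
    if not (lo <= lambda_max <= hi):
        warnings.warn(
            f"lambda_max {lambda_max} nm outside the calibrated template range "
            f"[{lo}, {hi}] nm",
            stacklevel=3,
        )


def _ssh_alpha_raw(wl, lambda_max: float):
    a, b, c = SSH_ALPHA["a"], SSH_ALPHA["b"], SSH_ALPHA["c"]
    x = np.log10(np.asarray(wl, dtype=float) / lambda_max)
    return np.exp(-a * x**2 * (1.0 + b * x + c * x**2))


def _gfkrd_alpha_raw(wl, lambda_max: float):
    p = GFKRD_ALPHA
    x = lambda_max / np.asarray(wl, dtype=float)
    a = p["a0"] + p["a1"] * np.exp(-((lambda_max - p["a2"]) ** 2) / p["a3"])
    denom = (
        np.exp(p["A"] * (a - x))
        + np.exp(p["B"] * (p["b"] - x))
        + np.exp(p["C"] * (p["c"] - x))
        + p["D"]
    )
    return 1.0 / denom


_RAW = {"SSH": _ssh_alpha_raw, "GFKRD": _gfkrd_alpha_raw}


def alpha_band(spec: PigmentSpec, wavelengths) -> np.ndarray:
    """Normalized alpha-band absorbance of ``spec`` on ``wavelengths``.

    Values lie in [0, 1] with the maximum attained at the grid point nearest
    λmax. Normalization divides by the template's value at λmax itself (or by
    the grid maximum in the rare case it exceeds it), so the peak is 1
    regardless of grid resolution.
    """
    wl = _check_grid(wavelengths)
    _warn_lambda_max(spec.lambda_max)
    raw_fn = _RAW[spec.family]
    raw = raw_fn(wl, spec.lambda_max)
    peak = max(float(raw_fn(spec.lambda_max, spec.lambda_max)), float(np.max(raw)))
    return raw / peak


def _alpha_matrix(
    family: str, lambda_maxes, wl: np.ndarray, include_beta: bool = False
) -> np.ndarray:
    """Normalized templates for several pigments at once, shape (m, len(wl)).

    Vectorized fast path for optimization loops: no grid checks, no range
    warnings, but numerically identical to :func:`alpha_band` /
    :func:`pigment_absorbance` rows (the SSH form peaks at exactly 1 at
    λmax; the GFKRD form is normalized by its value at λmax or the grid
    maximum, whichever is larger).
    """
    lams = np.atleast_1d(np.asarray(lambda_maxes, dtype=float))[:, None]
    row = wl[None, :]
    if family == "SSH":
        a, b, c = SSH_ALPHA["a"], SSH_ALPHA["b"], SSH_ALPHA["c"]
        x = np.log10(row / lams)
        # 1 + bx + cx^2 > 0 for all x (negative discriminant), so the raw
        # form never exceeds its value 1 at x = 0
        alpha = np.exp(-a * x**2 * (1.0 + b * x + c * x**2))
    elif family == "GFKRD":
        p = GFKRD_ALPHA
        x = lams / row
        av = p["a0"] + p["a1"] * np.exp(-((lams - p["a2"]) ** 2) / p["a3"])
        raw = 1.0 / (
            np.exp(p["A"] * (av - x))
            + np.exp(p["B"] * (p["b"] - x))
            + np.exp(p["C"] * (p["c"] - x))
            + p["D"]
        )
        peak_at_lmax = 1.0 / (
            np.exp(p["A"] * (av - 1.0))
            + np.exp(p["B"] * (p["b"] - 1.0))
            + np.exp(p["C"] * (p["c"] - 1.0))
            + p["D"]
        )
        peak = np.maximum(peak_at_lmax, raw.max(axis=1, keepdims=True))
        alpha = raw / peak
    else:
        raise UnsupportedTemplateError(f"unknown template family {family!r}")
    if not include_beta:
        return alpha
    bb = GFKRD_BETA
    lm = bb["lm0"] + bb["lm1"] * lams
    bw = bb["bw0"] + bb["bw1"] * lams
    combined = alpha + bb["amplitude"] * np.exp(-(((row - lm) / bw) ** 2))
    return combined / combined.max(axis=1, keepdims=True)


def _evaluate_nocheck(
    family: str, lambda_max: float, wl: np.ndarray, include_beta: bool = False
) -> np.ndarray:
    """Single-pigment row of :func:`_alpha_matrix`."""
    return _alpha_matrix(family, [lambda_max], wl, include_beta)[0]


def beta_band(spec: PigmentSpec, wavelengths) -> np.ndarray:
    """UV beta-band contribution, on the scale of an alpha peak of 1.

    Returns zeros when ``spec.include_beta`` is false. The band is a Gaussian
    whose centre (≈189 + 0.315·λmax nm) and width grow linearly with λmax;
    for any λmax ≥ 450 nm the peak sits below 420 nm.
    """
    wl = _check_grid(wavelengths)
    if not spec.include_beta:
        return np.zeros_like(wl)
    b = GFKRD_BETA
    lm = b["lm0"] + b["lm1"] * spec.lambda_max
    bw = b["bw0"] + b["bw1"] * spec.lambda_max
    return b["amplitude"] * np.exp(-(((wl - lm) / bw) ** 2))


def beta_peak_wavelength(spec: PigmentSpec) -> float:
    """Centre wavelength (nm) of the beta band for this pigment."""
    b = GFKRD_BETA
    return b["lm0"] + b["lm1"] * spec.lambda_max


def pigment_absorbance(spec: PigmentSpec, wavelengths) -> np.ndarray:
    """Combined alpha (+ optional beta) absorbance, renormalized to peak 1."""
    wl = _check_grid(wavelengths)
    alpha = alpha_band(spec, wl)
    if not spec.include_beta:
        return alpha
    combined = alpha + beta_band(spec, wl)
    return combined / float(np.max(combined))
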