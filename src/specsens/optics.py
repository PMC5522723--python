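"""Whole-array absorptance optics for fused, tiered photoreceptor arrays.

A photoreceptor array is modelled as a vertical stack of *tiers*, each a
fused cross-section of one or more receptor classes. Within a tier the
per-micrometre absorbance is

    ξ_j(λ) = Σ_i α_i(λ) · (A_i/A) · k_i ,

where α_i is the normalized pigment template, A_i/A the relative
cross-sectional area of receptor i and k_i its peak absorption coefficient
(μm⁻¹). Light traverses tiers distal → proximal; the fraction absorbed by
the whole array is

    S(λ) = Σ_j T_{j-1}(λ) · (1 − e^{−ξ_j(λ) l_j}) ,    T_0 = 1,

with T_j the transmittance through all preceding tiers. Absorptance saturates
with optical density k·l (self-screening), broadening the spectrum of long
photoreceptors. Pre-receptor filters (lens, macula, ellipsosomes) multiply
S(λ) by their transmittance before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .curves import SpectralCurve
from .exceptions import CurveError, StructuralError
from .templates import PigmentSpec, alpha_band, pigment_absorbance

# Peak absorption coefficients typical of dark-adapted photoreceptors, μm^-1.
DEFAULT_K_INVERTEBRATE = 0.008
DEFAULT_K_VERTEBRATE = 0.015


@dataclass(frozen=True)
class ReceptorClass:
    """One receptor class: pigment, relative cross-sectional area, and k."""

    pigment: PigmentSpec
    rel_area: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_area <= 1.0 + 1e-9):
            raise StructuralError(f"rel_area {self.rel_area} outside [0, 1]")
        if not (self.k > 0.0):
            raise StructuralError(f"k must be positive, got {self.k}")


@dataclass(frozen=True)
class Tier:
    """A vertical segment of the array: length (μm) and its receptor set.

    Relative areas are renormalized to sum to 1 within the tier on
    construction (published area sets occasionally sum to 1.05 or 1.01 from
    rounding or double-cone frequency corrections).
    """

    length_um: float
    receptors: tuple[ReceptorClass, ...]

    def __post_init__(self) -> None:
        if not (self.length_um > 0.0):
            raise StructuralError(f"tier length must be positive, got {self.length_um}")
        receptors = tuple(self.receptors)
        if not receptors:
            raise StructuralError("tier has no receptors")
        total = sum(r.rel_area for r in receptors)
        if total <= 0.0:
            raise StructuralError("tier relative areas sum to zero")
        if abs(total - 1.0) > 1e-9:
            receptors = tuple(
                replace(r, rel_area=r.rel_area / total) for r in receptors
            )
        object.__setattr__(self, "receptors", receptors)


@dataclass(frozen=True)
class ArrayStructure:
    """Tier layout shared by a family of candidate models.

    ``replace_shortest`` encodes the common insect/crustacean arrangement in
    which the shortest-wavelength receptor contributes only to the distal
    tier, becoming axon-like below it; its cross-sectional area is taken over
    by ``replacement_index`` (position among the remaining receptors,
    default the longest-wavelength one).
    """

    lengths_um: tuple[float, ...] = (100.0,)
    replace_shortest: bool = False
    replacement_index: int = -1

    def __post_init__(self) -> None:
        lengths = tuple(float(l) for l in self.lengths_um)
        if not lengths or any(l <= 0 for l in lengths):
            raise StructuralError(f"invalid tier lengths {lengths}")
        object.__setattr__(self, "lengths_um", lengths)

    @property
    def total_length_um(self) -> float:
        return float(sum(self.lengths_um))


@dataclass(frozen=True)
class EyeModel:
    """Ordered tiers (distal → proximal) plus pre-receptor filters."""

    tiers: tuple[Tier, ...]
    prefilters: tuple[SpectralCurve, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        tiers = tuple(self.tiers)
        if not tiers:
            raise StructuralError("eye model needs at least one tier")
        for pf in self.prefilters:
            if np.any(pf.values < -1e-12) or np.any(pf.values > 1.0 + 1e-12):
                raise CurveError("prefilter transmittance must lie in [0, 1]")
        object.__setattr__(self, "tiers", tiers)
        object.__setattr__(self, "prefilters", tuple(self.prefilters))

    @property
    def total_length_um(self) -> float:
        return float(sum(t.length_um for t in self.tiers))


def _tier_xi_values(tier: Tier, grid: np.ndarray) -> np.ndarray:
    xi = np.zeros_like(grid, dtype=float)
    for r in tier.receptors:
        if r.pigment.include_beta:
            alpha = pigment_absorbance(r.pigment, grid)
        else:
            alpha = alpha_band(r.pigment, grid)
        xi += alpha * r.rel_area * r.k
    return xi


def tier_xi(tier: Tier, grid) -> SpectralCurve:
    """Per-micrometre absorbance ξ_j(λ) of one tier (units μm⁻¹)."""
    grid = np.asarray(grid, dtype=float)
    return SpectralCurve(grid, _tier_xi_values(tier, grid))


def array_absorptance(model: EyeModel, grid) -> SpectralCurve:
    """Whole-array absorptance S(λ), before prefilters and normalization.

    S plus the residual transmittance Π_j e^{−ξ_j l_j} equals 1 pointwise:
    every photon is either absorbed in some tier or transmitted.
    """
    grid = np.asarray(grid, dtype=float)
    transmitted = np.ones_like(grid, dtype=float)
    absorbed = np.zeros_like(grid, dtype=float)
    for tier in model.tiers:
        tau = np.exp(-_tier_xi_values(tier, grid) * tier.length_um)
        absorbed += transmitted * (1.0 - tau)
        transmitted *= tau
    return SpectralCurve(grid, absorbed)


def residual_transmittance(model: EyeModel, grid) -> SpectralCurve:
    """Transmittance through the entire array, Π_j e^{−ξ_j l_j}."""
    grid = np.asarray(grid, dtype=float)
    transmitted = np.ones_like(grid, dtype=float)
    for tier in model.tiers:
        transmitted *= np.exp(-_tier_xi_values(tier, grid) * tier.length_um)
    return SpectralCurve(grid, transmitted)


def apply_prefilters(model: EyeModel, s: SpectralCurve) -> SpectralCurve:
    """Multiply S(λ) by every pre-receptor transmittance curve.

    Prefilters are resampled onto S's grid by linear interpolation, clamped
    to endpoint values outside their range (with a warning).
    """
    values = s.values.copy()
    for pf in model.prefilters:
        values *= pf.interp(s.wavelengths).values
    return SpectralCurve(s.wavelengths, values)


def normalize_peak(s: SpectralCurve) -> SpectralCurve:
    """Scale a spectrum so its maximum is 1 (shape and argmax preserved)."""
    return s.peak_normalized()


def cross_section_absorbance(model: EyeModel, grid, depth_fraction: float) -> SpectralCurve:
    """Thin-section absorbance at a relative depth along the array.

    Selects the tier containing ``depth_fraction`` of the total length
    (measured from the distal tip; a depth exactly on a tier boundary belongs
    to the distal side) and returns that tier's ξ_j(λ) normalized to peak 1.
    A thin section has no self-screening, so the spectrum is the absorbance
    mixture itself rather than the saturating absorptance.
    """
    if not (0.0 <= depth_fraction <= 1.0):
        raise StructuralError(f"depth_fraction {depth_fraction} outside [0, 1]")
    target = depth_fraction * model.total_length_um
    cumulative = 0.0
    chosen = model.tiers[-1]
    for tier in model.tiers:
        cumulative += tier.length_um
        if target <= cumulative + 1e-9:
            chosen = tier
            break
    return tier_xi(chosen, grid).peak_normalized()


# ---------------------------------------------------------------------------
# Model construction and (de)serialization


def build_eye_model(
    family: str,
    lambdas,
    areas,
    ks,
    structure: ArrayStructure,
    prefilters: tuple[SpectralCurve, ...] = (),
    include_beta: bool = False,
    label: str = "",
) -> EyeModel:
    """Assemble an EyeModel from per-class parameters and a tier layout.

    ``lambdas`` must be sorted ascending; ``ks`` may be a scalar (shared k)
    or one value per class. With ``structure.replace_shortest`` and more than
    one class, tiers after the first drop the shortest-wavelength receptor
    and hand its area to the replacement receptor, keeping other fractions.
    """
    lambdas = [float(l) for l in lambdas]
    areas = [float(a) for a in areas]
    m = len(lambdas)
    if len(areas) != m:
        raise StructuralError(f"{m} lambdas but {len(areas)} areas")
    ks = [float(k) for k in (ks if np.ndim(ks) else [ks] * m)]
    if len(ks) != m:
        raise StructuralError(f"{m} lambdas but {len(ks)} k values")
    if any(l2 <= l1 for l1, l2 in zip(lambdas, lambdas[1:])):
        raise StructuralError("lambdas must be strictly increasing")

    def receptors(lams, ars, kvals):
        total = sum(ars)
        return tuple(
            ReceptorClass(PigmentSpec(family, lam, include_beta), a / total, k)
            for lam, a, k in zip(lams, ars, kvals)
        )

    tiers = [Tier(structure.lengths_um[0], receptors(lambdas, areas, ks))]
    for length in structure.lengths_um[1:]:
        if structure.replace_shortest and m > 1:
            sub_areas = list(areas[1:])
            sub_areas[structure.replacement_index] += areas[0]
            tiers.append(Tier(length, receptors(lambdas[1:], sub_areas, ks[1:])))
        else:
            tiers.append(Tier(length, receptors(lambdas, areas, ks)))
    return EyeModel(tuple(tiers), prefilters, label)


def eye_model_to_dict(model: EyeModel) -> dict:
    return {
        "label": model.label,
        "tiers": [
            {
                "length_um": t.length_um,
                "receptors": [
                    {
                        "family": r.pigment.family,
                        "lambda_max": r.pigment.lambda_max,
                        "include_beta": r.pigment.include_beta,
                        "rel_area": r.rel_area,
                        "k": r.k,
                    }
                    for r in t.receptors
                ],
            }
            for t in model.tiers
        ],
    }


def eye_model_from_dict(d: dict, prefilters: tuple[SpectralCurve, ...] = ()) -> EyeModel:
    tiers = tuple(
        Tier(
            float(td["length_um"]),
            tuple(
                ReceptorClass(
                    PigmentSpec(
                        rd["family"],
                        float(rd["lambda_max"]),
                        bool(rd.get("include_beta", False)),
                    ),
                    float(rd["rel_area"]),
                    float(rd["k"]),
                )
                for rd in td["receptors"]
            ),
        )
        for td in d["tiers"]
    )
    return EyeModel(tiers, prefilters, str(d.get("label", "")))


def save_eye_model(model: EyeModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(eye_model_to_dict(model), fh, sort_keys=False)


def load_eye_model(path, prefilters: tuple[SpectralCurve, ...] = ()) -> EyeModel:
    with open(path) as fh:
        return eye_model_from_dict(yaml.safe_load(fh), prefilters)
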