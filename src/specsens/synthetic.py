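"""Synthetic spectral sensitivity scenarios with known ground truth.

The generator emulates the kind of data this framework consumes: relative
spectral sensitivities binned at 20 nm over ranges such as 310–690 nm,
produced by a known photoreceptor array and corrupted by additive Gaussian
noise on the relative-sensitivity scale (the default sd of 0.02 is an
arbitrary but visually realistic choice for extracellular ERG scatter).
Optionally several "eye regions" are simulated as independent noisy copies
and averaged, mirroring multi-region recording protocols.

`scenario_library` packages study systems spanning one to five spectral
classes — a velvet-worm-like single-class eye, a human-like scotopic duplex
retina behind lens and macular filters, a Daphnia-like tiered four-class
ommatidium, a Papilio-like five-class long tiered rhabdom (in both
absorptance and thin-section absorbance modes), and a killifish-like
fixed-array eye for absorption-coefficient (k) fitting. Truth parameters
follow published values for those systems; pre-receptor filter curves are
synthetic stand-ins (smooth sigmoid lens cut-off, Gaussian pigment bands),
not digitized literature curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import SpectralCurve
from .exceptions import SpecsensError
from .fitting import FitProblem, _Objective
from .optics import ArrayStructure, build_eye_model, EyeModel

DEFAULT_NOISE_SD = 0.02


def synthetic_lens_transmittance(
    cutoff_nm: float = 400.0, width_nm: float = 12.0,
    grid=(300.0, 750.0),
) -> SpectralCurve:
    """Synthetic ocular-lens transmittance: sigmoid cut-off of UV light."""
    wl = np.arange(grid[0], grid[1] + 0.5, 1.0)
    return SpectralCurve(wl, 1.0 / (1.0 + np.exp(-(wl - cutoff_nm) / width_nm)))


def synthetic_pigment_band_transmittance(
    center_nm: float, width_nm: float, peak_density: float,
    grid=(300.0, 750.0),
) -> SpectralCurve:
    """Synthetic absorbing-layer transmittance: 10^(−D·Gaussian band).

    Stands in for macular pigment (center ≈ 460 nm) or ellipsosome
    (heme-like, center ≈ 415 nm) screening.
    """
    wl = np.arange(grid[0], grid[1] + 0.5, 1.0)
    density = peak_density * np.exp(-(((wl - center_nm) / width_nm) ** 2))
    return SpectralCurve(wl, 10.0 ** (-density))


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth eye plus the sampling scheme used to observe it."""

    name: str
    family: str
    lambdas: tuple[float, ...]
    areas: tuple[float, ...]
    k: float | tuple[float, ...]
    structure: ArrayStructure
    grid_range: tuple[float, float]
    prefilters: tuple[SpectralCurve, ...] = ()
    bin_interval: float = 20.0
    noise_sd: float = DEFAULT_NOISE_SD
    n_regions: int = 1
    seed: int = 0
    mode: str = "absorptance"
    depth_fraction: float = 2.0 / 3.0
    free: str = "lambda_areas"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecsensError("noise_sd must be >= 0")
        lo, hi = self.grid_range
        if not (lo < hi) or (hi - lo) % self.bin_interval > 1e-9:
            raise SpecsensError(f"invalid grid range {self.grid_range}")

    @property
    def n_classes(self) -> int:
        return len(self.lambdas)

    def truth_model(self) -> EyeModel:
        return build_eye_model(
            self.family,
            self.lambdas,
            self.areas,
            self.k,
            self.structure,
            self.prefilters,
            label=self.name,
        )

    def truth_record(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "n_classes": self.n_classes,
            "lambdas": list(self.lambdas),
            "areas": [a / sum(self.areas) for a in self.areas],
            "k": list(np.atleast_1d(self.k).astype(float)),
            "mode": self.mode,
            "structure": {
                "lengths_um": list(self.structure.lengths_um),
                "replace_shortest": self.structure.replace_shortest,
            },
            "grid_range": list(self.grid_range),
            "bin_interval": self.bin_interval,
            "noise_sd": self.noise_sd,
            "n_regions": self.n_regions,
        }


def truth_curve(scenario: SyntheticScenario) -> SpectralCurve:
    """Noise-free model curve on the scenario's binned grid."""
    data_grid = np.arange(
        scenario.grid_range[0],
        scenario.grid_range[1] + scenario.bin_interval / 2,
        scenario.bin_interval,
    )
    # reuse the fitting forward model so generator and fits share one optics path
    placeholder = SpectralCurve(data_grid, np.ones_like(data_grid))
    problem = FitProblem(
        data=placeholder,
        family=scenario.family,
        n_classes=scenario.n_classes,
        structure=scenario.structure,
        k=scenario.k if np.ndim(scenario.k) == 0 else tuple(scenario.k),
        prefilters=scenario.prefilters,
        mode=scenario.mode,
        free="k",
        lambdas=scenario.lambdas,
        areas=scenario.areas,
    )
    obj = _Objective(problem)
    ks = np.atleast_1d(np.asarray(scenario.k, dtype=float))
    if ks.size == 1:
        ks = np.repeat(ks, scenario.n_classes)
    vals = obj.sample(obj.model_values(obj.fixed_lambdas, obj.fixed_areas, ks))
    peak = vals.max()
    return SpectralCurve(data_grid, vals / peak if peak > 0 else vals)


def generate(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[SpectralCurve, dict]:
    """Simulate one observed dataset: truth curve + noise, clipped at 0.

    Regions (if ``n_regions > 1``) are independent noisy realizations that
    are averaged before the final peak renormalization, as a multi-region
    recording would be. Reproducible for a given seed.
    """
    clean = truth_curve(scenario)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    noisy = np.mean(
        [
            clean.values + rng.normal(0.0, scenario.noise_sd, clean.n)
            for _ in range(scenario.n_regions)
        ],
        axis=0,
    )
    noisy = np.clip(noisy, 0.0, None)
    peak = noisy.max()
    if peak > 0:
        noisy = noisy / peak
    record = scenario.truth_record()
    record["seed"] = scenario.seed if seed is None else seed
    return SpectralCurve(clean.wavelengths, noisy), record


def scenario_library() -> dict[str, SyntheticScenario]:
    """Named study scenarios spanning one to five spectral classes."""
    lens_human = synthetic_lens_transmittance(cutoff_nm=400.0, width_nm=10.0)
    macula = synthetic_pigment_band_transmittance(460.0, 45.0, 0.5)
    lens_fish = synthetic_lens_transmittance(cutoff_nm=380.0, width_nm=12.0)
    ellipsosome = synthetic_pigment_band_transmittance(415.0, 40.0, 0.3)

    papilio = dict(
        family="GFKRD",
        lambdas=(360.0, 390.0, 460.0, 520.0, 600.0),
        areas=(0.10, 0.25, 0.32, 0.20, 0.12),
        k=0.008,
        structure=ArrayStructure(
            (1000.0 / 3.0, 500.0 / 3.0), replace_shortest=True
        ),
        grid_range=(310.0, 690.0),
        n_regions=3,
    )

    return {
        "velvet_worm": SyntheticScenario(
            name="velvet_worm",
            family="GFKRD",
            lambdas=(481.0,),
            areas=(1.0,),
            k=0.008,
            structure=ArrayStructure((100.0,)),
            grid_range=(350.0, 690.0),
        ),
        "human_scotopic": SyntheticScenario(
            name="human_scotopic",
            family="SSH",
            lambdas=(420.0, 497.0),
            areas=(0.16, 0.84),
            k=0.015,
            structure=ArrayStructure((22.5,)),
            grid_range=(410.0, 690.0),
            prefilters=(lens_human, macula),
        ),
        "daphnia": SyntheticScenario(
            name="daphnia",
            family="SSH",
            lambdas=(356.0, 440.0, 521.0, 592.0),
            areas=(0.52, 0.21, 0.12, 0.15),
            k=0.008,
            structure=ArrayStructure((6.0, 6.0), replace_shortest=True),
            grid_range=(350.0, 690.0),
        ),
        "papilio_absorptance": SyntheticScenario(
            name="papilio_absorptance", mode="absorptance", **papilio
        ),
        "papilio_absorbance": SyntheticScenario(
            name="papilio_absorbance", mode="absorbance", **papilio
        ),
        "killifish_spring": SyntheticScenario(
            name="killifish_spring",
            family="SSH",
            lambdas=(359.0, 405.0, 454.0, 538.0, 572.0),
            areas=(0.08, 0.31, 0.16, 0.25, 0.25),
            # spring-population truth: SWS2A is expressed at a negligible level
            k=(0.0030, 0.0051, 1e-6, 0.0050, 0.0032),
            structure=ArrayStructure((18.0,)),
            grid_range=(350.0, 690.0),
            prefilters=(lens_fish, ellipsosome),
            free="k",
        ),
    }
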