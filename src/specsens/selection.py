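"""Likelihood scoring and AICc multi-model selection.

Models are compared on a shared binned sensitivity vector of length n by
their residual sum of squares (RSS) under an i.i.d. Gaussian error model.
The concentrated (profile) log-likelihood at the MLE σ̂² = RSS/n is

    log L = −(n/2)·ln(RSS/n) − (n/2)·ln(2π) − n/2 ,

and the small-sample Akaike criterion is

    AICc = −2·log L + 2K + 2K(K+1)/(n − K − 1) ,

with K the parameter count (per-class λmax and area plus the residual
variance for class-count models; per-pigment k plus the variance for
fixed-array concentration models). Candidate models are ranked by
ΔAICc = AICc − min AICc; Akaike weights w_i = e^{−Δ_i/2}/Σ_r e^{−Δ_r/2}
and evidence ratios w_best/w_i = e^{Δ_i/2} express relative support.

Lower AICc is better throughout. Published tables in this literature often
print the magnitude |AICc| of a negative score and rank on that instead;
``SelectionTable.to_frame`` carries an ``aicc_printed`` column for direct
comparison with such tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import SpectralCurve
from .exceptions import (
    IncompatibleFitsError,
    InfiniteLikelihoodError,
    SpecsensError,
)
from .optics import ArrayStructure, EyeModel

# Floor applied to RSS before likelihood evaluation, to keep pathological
# exact fits from producing an unbounded likelihood.
RSS_FLOOR = 1e-12


def log_likelihood(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood given RSS over n points."""
    if n < 2:
        raise SpecsensError(f"need n >= 2 data points, got {n}")
    if rss <= 0.0:
        raise InfiniteLikelihoodError(
            "RSS <= 0 gives an unbounded likelihood; floor the RSS "
            f"(e.g. at {RSS_FLOOR}) or jitter the data"
        )
    sigma2 = rss / n
    return -0.5 * n * math.log(sigma2) - 0.5 * n * math.log(2.0 * math.pi) - 0.5 * n


def aicc(logL: float, K: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion (lower = better)."""
    if n <= K + 1:
        raise SpecsensError(
            f"AICc correction undefined for n={n}, K={K} (need n > K + 1)"
        )
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def evidence_ratio(delta: float) -> float:
    """Evidence ratio of the best model over a model with ΔAICc = delta."""
    if delta < -1e-9:
        raise SpecsensError(f"delta must be >= 0, got {delta}")
    return math.exp(0.5 * max(delta, 0.0))


def nested_f_test(
    rss_small_k: float,
    k_small: int,
    rss_large_k: float,
    k_large: int,
    n: int,
) -> tuple[float, float]:
    """Extra-sum-of-squares F-test between nested nonlinear regressions.

    Returns (F, p) with F = ((RSS_s − RSS_l)/(K_l − K_s)) / (RSS_l/(n − K_l))
    and p the upper tail of F(K_l − K_s, n − K_l). p < 0.05 favours the
    larger model.
    """
    if k_large <= k_small:
        raise SpecsensError(f"K_large ({k_large}) must exceed K_small ({k_small})")
    if n <= k_large:
        raise SpecsensError(f"degenerate degrees of freedom: n={n}, K_large={k_large}")
    if rss_large_k <= 0:
        raise SpecsensError("RSS of the larger model must be positive")
    if rss_large_k > rss_small_k:
        import warnings

        warnings.warn(
            "larger model has larger RSS; it is not a refinement of the smaller",
            stacklevel=2,
        )
    df1 = k_large - k_small
    df2 = n - k_large
    f_stat = ((rss_small_k - rss_large_k) / df1) / (rss_large_k / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), p


# ---------------------------------------------------------------------------
# Fit records and the selection table


@dataclass(frozen=True)
class ModelFit:
    """One scored model: fitted parameters plus its likelihood bookkeeping."""

    label: str
    rss: float
    n: int
    K: int
    logL: float
    aicc: float
    family: str = ""
    n_classes: int = 0
    mode: str = "absorptance"
    lambdas: tuple[float, ...] = ()
    areas: tuple[float, ...] = ()
    ks: tuple[float, ...] = ()
    model: EyeModel | None = None
    predicted: SpectralCurve | None = None
    data: SpectralCurve | None = None
    at_k_bounds: tuple[bool, ...] = ()
    n_starts: int = 1
    seed: int | None = None
    start_diagnostics: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise SpecsensError(f"negative RSS {self.rss}")
        if self.K < 2:
            raise SpecsensError(f"K must be >= 2 (variance + >=1 parameter), got {self.K}")
        if self.n <= self.K + 1:
            raise SpecsensError(f"need n > K + 1 for AICc (n={self.n}, K={self.K})")

    @property
    def k_normalized(self) -> tuple[float, ...]:
        """Absorption coefficients normalized by their sum, k_i / Σk."""
        total = sum(self.ks)
        if total <= 0:
            return ()
        return tuple(k / total for k in self.ks)


def score_fit(rss: float, K: int, n: int) -> tuple[float, float]:
    """(logL, AICc) from an RSS, applying the RSS floor."""
    ll = log_likelihood(max(rss, RSS_FLOOR), n)
    return ll, aicc(ll, K, n)


@dataclass(frozen=True)
class SelectionTable:
    """Candidate fits with ΔAICc, Akaike weights and evidence ratios."""

    fits: tuple[ModelFit, ...]
    delta: tuple[float, ...]
    weights: tuple[float, ...]
    evidence: tuple[float, ...]

    @property
    def best(self) -> ModelFit:
        return self.fits[int(np.argmin(self.delta))]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view mirroring published model-comparison tables."""
        rows = []
        for fit, d, w, ev in zip(self.fits, self.delta, self.weights, self.evidence):
            row = {
                "model": fit.label,
                "classes": " ".join(
                    f"{lam:.0f} ({a:.2f})" for lam, a in zip(fit.lambdas, fit.areas)
                ),
                "rss": fit.rss,
                "K": fit.K,
                "aicc": fit.aicc,
                # published tables print the magnitude of (negative) AICc
                "aicc_printed": abs(fit.aicc),
                "delta_aicc": d,
                "weight": w,
                "evidence_ratio": ev,
            }
            if fit.ks and fit.mode != "absorbance":
                row["k"] = " ".join(f"{k:.4g}" for k in fit.ks)
                if fit.k_normalized:
                    row["k_normalized"] = " ".join(
                        f"{k:.2f}" for k in fit.k_normalized
                    )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, index=False, sep=sep)


def selection_table(fits: list[ModelFit]) -> SelectionTable:
    """Rank fits of the same data by AICc.

    All fits must share n and (when attached) the same data vector.
    """
    if not fits:
        raise SpecsensError("selection_table needs at least one fit")
    n0 = fits[0].n
    ref_data = next((f.data for f in fits if f.data is not None), None)
    for f in fits:
        if f.n != n0:
            raise IncompatibleFitsError(
                f"fits scored on different n: {f.n} vs {n0}"
            )
        if f.data is not None and ref_data is not None:
            if not (
                np.array_equal(f.data.wavelengths, ref_data.wavelengths)
                and np.array_equal(f.data.values, ref_data.values)
            ):
                raise IncompatibleFitsError("fits scored on different data vectors")
    scores = np.array([f.aicc for f in fits])
    delta = scores - scores.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    ev = np.exp(0.5 * delta)
    return SelectionTable(tuple(fits), tuple(delta), tuple(w), tuple(ev))


# ---------------------------------------------------------------------------
# Candidate enumeration


@dataclass(frozen=True)
class CandidateConfig:
    """Describes the model universe for one dataset.

    ``structure`` carries the known tier layout; a tiered layout with
    ``replace_shortest`` is applied to every candidate with more than one
    class (with one class the replacement is a no-op). ``mode`` selects
    whole-array absorptance or thin-section absorbance fitting.
    """

    max_classes: int = 5
    families: tuple[str, ...] = ("SSH", "GFKRD")
    structure: ArrayStructure = ArrayStructure()
    k: float = 0.008
    mode: str = "absorptance"
    depth_fraction: float = 2.0 / 3.0
    include_beta: bool = False
    prefilters: tuple[SpectralCurve, ...] = ()
    lambda_bounds: tuple[float, float] | None = None


@dataclass(frozen=True)
class CandidateSpec:
    label: str
    n_classes: int
    family: str


def enumerate_candidates(config: CandidateConfig) -> list[CandidateSpec]:
    """Deterministic candidate list: class count ascending, SSH before GFKRD."""
    if config.max_classes < 1:
        raise SpecsensError("max_classes must be >= 1")
    order = [f for f in ("SSH", "GFKRD") if f in config.families]
    order += [f for f in config.families if f not in order]
    return [
        CandidateSpec(f"{m}, {family}", m, family)
        for m in range(1, config.max_classes + 1)
        for family in order
    ]
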