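"""Constrained least-squares fitting of eye models to sensitivity data.

Free parameters are optimized by bounded trust-region least squares
(``scipy.optimize.least_squares``) from multiple seeded Latin-hypercube
starts, in a transformed space that makes the constraints smooth:

* λmax values are parameterized as (λ1, positive gaps), so the ordering
  constraint λmax_i < λmax_{i+1} holds everywhere in the feasible box
  (minimum separation 0.1 nm);
* relative areas live on the simplex via a softmax of m−1 logits, so they
  sum to 1 exactly;
* absorption coefficients are optimized in log10 space within their bounds
  (default 0.001–1.0 μm⁻¹).

The residual is the difference between the peak-normalized model spectrum,
evaluated on a 1 nm internal grid and sampled down to the binned data grid,
and the peak-normalized data. Computing on the fine grid first avoids the
argmax and bandwidth distortion that coarse-grid evaluation would cause.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .curves import SpectralCurve
from .exceptions import ConvergenceError, InfeasibleProblemError, SpecsensError
from .optics import ArrayStructure, build_eye_model
from .selection import ModelFit, score_fit
from .templates import _alpha_matrix

DEFAULT_N_STARTS = 32
MIN_SEPARATION_NM = 0.1
LAMBDA_HARD_BOUNDS = (310.0, 650.0)
# weight of the soft penalty pulling the longest lambda back inside bounds
_ORDER_PENALTY = 0.05


@dataclass(frozen=True)
class FitProblem:
    """A dataset, a model family/structure, and which parameters are free.

    ``free`` is ``"lambda_areas"`` (λmax and areas free, k fixed — class
    identification) or ``"k"`` (λmax and areas fixed constants, per-pigment
    k free — concentration mapping). ``lambdas``/``areas`` supply the fixed
    constants in the latter case and are ignored in the former.
    """

    data: SpectralCurve
    family: str
    n_classes: int
    structure: ArrayStructure = ArrayStructure()
    k: float | tuple[float, ...] = 0.008
    prefilters: tuple[SpectralCurve, ...] = ()
    mode: str = "absorptance"  # or "absorbance" (thin section, no screening)
    free: str = "lambda_areas"
    lambdas: tuple[float, ...] = ()
    areas: tuple[float, ...] = ()
    lambda_bounds: tuple[float, float] | None = None
    k_bounds: tuple[float, float] = (0.001, 1.0)
    ordering: bool = True
    include_beta: bool = False
    min_sep: float = MIN_SEPARATION_NM
    n_starts: int = DEFAULT_N_STARTS
    seed: int | np.random.Generator = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.free not in ("lambda_areas", "k"):
            raise SpecsensError(f"unknown free-parameter set {self.free!r}")
        if self.n_classes < 1:
            raise SpecsensError("need at least one receptor class")
        if self.mode not in ("absorptance", "absorbance"):
            raise SpecsensError(f"unknown mode {self.mode!r}")
        if self.free == "k":
            if len(self.lambdas) != self.n_classes or len(self.areas) != self.n_classes:
                raise SpecsensError(
                    "free='k' requires fixed lambdas and areas, one per class"
                )
            if not (0 < self.k_bounds[0] < self.k_bounds[1]):
                raise InfeasibleProblemError(f"bad k bounds {self.k_bounds}")
        if self.data.n < self.K + 2:
            raise SpecsensError(
                f"data has {self.data.n} points; need at least K+2 = {self.K + 2}"
            )

    @property
    def K(self) -> int:
        """Parameter count for AICc: 2m+1 for class models, m+1 for k models.

        The class-model convention counts a λmax and an area per class plus
        the residual variance even though the areas carry only m−1 degrees
        of freedom; this matches the bookkeeping used in published tables
        (1 class → K=3, ..., 5 classes → K=11).
        """
        if self.free == "k":
            return self.n_classes + 1
        return 2 * self.n_classes + 1

    def resolved_lambda_bounds(self) -> tuple[float, float]:
        """λmax bounds: data range ± 30 nm, clipped to the hard template box."""
        if self.lambda_bounds is not None:
            lo, hi = self.lambda_bounds
        else:
            lo = max(LAMBDA_HARD_BOUNDS[0], float(self.data.wavelengths[0]) - 30.0)
            hi = min(LAMBDA_HARD_BOUNDS[1], float(self.data.wavelengths[-1]) + 30.0)
        if not (lo < hi):
            raise InfeasibleProblemError(f"empty lambda bounds ({lo}, {hi})")
        return lo, hi

    def k_vector(self) -> tuple[float, ...]:
        if np.ndim(self.k):
            ks = tuple(float(v) for v in np.atleast_1d(self.k))
            if len(ks) != self.n_classes:
                raise SpecsensError(f"{len(ks)} k values for {self.n_classes} classes")
            return ks
        return (float(self.k),) * self.n_classes


@dataclass(frozen=True)
class StartResult:
    """Outcome of one local optimization (diagnostic record)."""

    theta: np.ndarray
    rss: float
    success: bool
    nfev: int
    message: str


def _softmax(z: np.ndarray) -> np.ndarray:
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


class _Objective:
    """Residual function with pre-resolved grids and prefilter products."""

    def __init__(self, problem: FitProblem):
        self.p = problem
        data = problem.data
        w0, w1 = float(data.wavelengths[0]), float(data.wavelengths[-1])
        self.grid = np.arange(w0, w1 + 0.5, 1.0)
        # binned data normally sits exactly on the 1 nm grid; fall back to
        # interpolation otherwise
        idx = np.round(data.wavelengths - w0).astype(int)
        idx = np.clip(idx, 0, self.grid.size - 1)
        if np.allclose(self.grid[idx], data.wavelengths, atol=1e-9):
            self.sample = lambda vals: vals[idx]
        else:
            self.sample = lambda vals: np.interp(
                data.wavelengths, self.grid, vals
            )
        self.y = data.values
        pf = np.ones_like(self.grid)
        for curve in problem.prefilters:
            pf *= curve.interp(self.grid, warn_extrapolate=False).values
        self.prefilter = pf
        self.m = problem.n_classes
        self.lambda_lo, self.lambda_hi = problem.resolved_lambda_bounds()
        if problem.free == "k":
            self.fixed_lambdas = np.asarray(problem.lambdas, dtype=float)
            total = float(np.sum(problem.areas))
            self.fixed_areas = np.asarray(problem.areas, dtype=float) / total
            self.fixed_ks = None
        else:
            self.fixed_ks = np.asarray(problem.k_vector(), dtype=float)

    # -- parameter packing ------------------------------------------------

    def unpack(self, theta: np.ndarray):
        p = self.p
        if p.free == "k":
            ks = 10.0 ** np.asarray(theta, dtype=float)
            return self.fixed_lambdas, self.fixed_areas, ks
        m = self.m
        lams = theta[0] + np.concatenate([[0.0], np.cumsum(theta[1:m])])
        areas = _softmax(np.asarray(theta[m:], dtype=float)) if m > 1 else np.ones(1)
        return lams, areas, self.fixed_ks

    def bounds(self):
        p = self.p
        if p.free == "k":
            lo = math.log10(p.k_bounds[0])
            hi = math.log10(p.k_bounds[1])
            return np.full(self.m, lo), np.full(self.m, hi)
        m = self.m
        lo_l, hi_l = self.lambda_lo, self.lambda_hi
        span = hi_l - lo_l
        if p.min_sep * (m - 1) > span:
            raise InfeasibleProblemError(
                f"{m} classes with min separation {p.min_sep} nm do not fit in "
                f"lambda bounds ({lo_l}, {hi_l})"
            )
        lo = np.concatenate([[lo_l], np.full(m - 1, p.min_sep), np.full(m - 1, -8.0)])
        hi = np.concatenate([[hi_l], np.full(m - 1, span), np.full(m - 1, 8.0)])
        return lo, hi

    def starts(self, n_starts: int, rng: np.random.Generator) -> np.ndarray:
        p = self.p
        m = self.m
        if p.free == "k":
            lo, hi = self.bounds()
            unit = qmc.LatinHypercube(d=self.m, seed=rng).random(n_starts)
            return lo + unit * (hi - lo)
        d = 2 * m - 1
        unit = qmc.LatinHypercube(d=d, seed=rng).random(n_starts)
        lo_l, hi_l = self.lambda_lo, self.lambda_hi
        span = hi_l - lo_l
        starts = np.empty((n_starts, d))
        gap_hi = span / max(m - 1, 1)
        starts[:, 1:m] = p.min_sep + unit[:, 1:m] * (gap_hi - p.min_sep)
        # ordering-feasible repair: keep lambda_1 low enough that the last
        # class stays inside the bounds
        total_gap = starts[:, 1:m].sum(axis=1)
        starts[:, 0] = lo_l + unit[:, 0] * np.maximum(hi_l - total_gap - lo_l, 1.0)
        starts[:, m:] = -2.0 + 4.0 * unit[:, m:]
        return starts

    # -- model evaluation -------------------------------------------------

    def model_values(self, lams, areas, ks) -> np.ndarray:
        """Peak-normalized model spectrum on the internal 1 nm grid."""
        p = self.p
        alphas = _alpha_matrix(p.family, lams, self.grid, p.include_beta)
        m = alphas.shape[0]
        weights = np.asarray(areas, dtype=float) * np.asarray(ks, dtype=float)
        if p.mode == "absorbance":
            xi = weights @ alphas
            peak = xi.max()
            return xi / peak if peak > 0 else xi
        structure = p.structure
        transmitted = 1.0
        absorbed = 0.0
        for j, length in enumerate(structure.lengths_um):
            if j > 0 and structure.replace_shortest and m > 1:
                tier_areas = np.array(areas[1:], dtype=float)
                tier_areas[structure.replacement_index] += areas[0]
                xi = (tier_areas * np.asarray(ks[1:], dtype=float)) @ alphas[1:]
            else:
                xi = weights @ alphas
            tau = np.exp(-xi * length)
            absorbed = absorbed + transmitted * (1.0 - tau)
            transmitted = transmitted * tau
        absorbed = absorbed * self.prefilter
        peak = absorbed.max()
        return absorbed / peak if peak > 0 else absorbed

    def predict(self, lams, areas, ks) -> np.ndarray:
        """Model values sampled to the data grid, peak-normalized there.

        RSS is defined between the peak-normalized model and the
        peak-normalized data on the binned grid, so the sampled curve is
        renormalized after downsampling.
        """
        sampled = self.sample(self.model_values(lams, areas, ks))
        peak = sampled.max()
        return sampled / peak if peak > 0 else sampled

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        lams, areas, ks = self.unpack(theta)
        r = self.predict(lams, areas, ks) - self.y
        if self.p.free == "k":
            return r
        # soft pull-back when the gap parameterization pushes the longest
        # class past the upper lambda bound
        excess = max(float(lams[-1]) - self.lambda_hi, 0.0)
        return np.concatenate([r, [_ORDER_PENALTY * excess]])

    def rss(self, theta: np.ndarray) -> float:
        lams, areas, ks = self.unpack(theta)
        r = self.predict(lams, areas, ks) - self.y
        return float(np.dot(r, r))


def _run_starts(problem: FitProblem, n_starts: int) -> list[StartResult]:
    obj = _Objective(problem)
    lo, hi = obj.bounds()
    rng = (
        problem.seed
        if isinstance(problem.seed, np.random.Generator)
        else np.random.default_rng(problem.seed)
    )
    starts = obj.starts(n_starts, rng)
    results: list[StartResult] = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                obj.residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                ftol=1e-8,
                xtol=1e-8,
                gtol=1e-8,
                max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - defensive
            results.append(StartResult(x0, float("inf"), False, 0, str(exc)))
            continue
        results.append(
            StartResult(res.x, obj.rss(res.x), res.status > 0, res.nfev, res.message)
        )
    if not any(r.success for r in results):
        raise ConvergenceError(
            f"optimizer failed on all {n_starts} starts: "
            + "; ".join(sorted({r.message for r in results}))
        )
    return results


def _finalize(
    problem: FitProblem, best: StartResult, all_results: list[StartResult]
) -> ModelFit:
    obj = _Objective(problem)
    lams, areas, ks = obj.unpack(best.theta)
    logL, aicc_val = score_fit(best.rss, problem.K, problem.data.n)
    model = build_eye_model(
        problem.family,
        lams,
        areas,
        ks,
        problem.structure if problem.mode == "absorptance" else ArrayStructure((1.0,)),
        problem.prefilters,
        problem.include_beta,
        problem.label,
    )
    predicted = SpectralCurve(
        problem.data.wavelengths, obj.predict(lams, areas, ks)
    )
    at_bounds = ()
    if problem.free == "k":
        lo, hi = problem.k_bounds
        at_bounds = tuple(
            bool(k <= lo * (1 + 1e-6) or k >= hi * (1 - 1e-6)) for k in ks
        )
    label = problem.label or f"{problem.n_classes}, {problem.family}"
    return ModelFit(
        label=label,
        rss=float(best.rss),
        n=problem.data.n,
        K=problem.K,
        logL=logL,
        aicc=aicc_val,
        family=problem.family,
        n_classes=problem.n_classes,
        mode=problem.mode,
        lambdas=tuple(float(v) for v in lams),
        areas=tuple(float(v) for v in areas),
        ks=tuple(float(v) for v in ks),
        model=model,
        predicted=predicted,
        data=problem.data,
        at_k_bounds=at_bounds,
        n_starts=len(all_results),
        seed=problem.seed if isinstance(problem.seed, int) else None,
        start_diagnostics=tuple(
            (r.rss, r.success, r.nfev) for r in all_results
        ),
    )


def fit(problem: FitProblem) -> ModelFit:
    """Best local optimum over all Latin-hypercube starts.

    Deterministic for a given (problem, seed); the reported RSS is computed
    on the data grid without the soft constraint penalty.
    """
    results = _run_starts(problem, problem.n_starts)
    best = min(results, key=lambda r: (not r.success, r.rss))
    return _finalize(problem, best, results)


def fit_k(problem: FitProblem) -> ModelFit:
    """Fit per-pigment absorption coefficients with λmax and areas fixed.

    The returned fit carries the raw k vector, a normalized version
    (k_i / Σk, comparable to relative opsin expression) and flags for
    coefficients pinned at their bounds.
    """
    if problem.free != "k":
        problem = replace(problem, free="k")
    return fit(problem)


def multi_start(problem: FitProblem, n_starts: int | None = None) -> list[ModelFit]:
    """All local optima as individual ModelFits, for diagnostics.

    ``fit`` is the n_starts-way minimum of this list by RSS.
    """
    n = problem.n_starts if n_starts is None else n_starts
    if n < 1:
        raise SpecsensError("n_starts must be >= 1")
    results = _run_starts(problem, n)
    return [_finalize(problem, r, [r]) for r in results]
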