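"""End-to-end candidate sweep: enumerate, fit, and rank models for a dataset."""

from __future__ import annotations

import warnings

import numpy as np

from .curves import SpectralCurve
from .fitting import DEFAULT_N_STARTS, FitProblem, fit
from .selection import (
    CandidateConfig,
    ModelFit,
    SelectionTable,
    enumerate_candidates,
    selection_table,
)


def fit_candidates(
    data: SpectralCurve,
    config: CandidateConfig,
    seed: int = 0,
    n_starts: int = DEFAULT_N_STARTS,
) -> SelectionTable:
    """Fit every candidate in ``config``'s model universe and rank by AICc.

    Candidates whose parameter count is too large for the data (n ≤ K + 1,
    where AICc is undefined) are skipped with a warning. Each candidate gets
    an independent child seed derived from ``seed`` so results are
    reproducible yet starts are not shared across candidates.
    """
    fits: list[ModelFit] = []
    for idx, cand in enumerate(enumerate_candidates(config)):
        K = 2 * cand.n_classes + 1
        if data.n <= K + 1:
            warnings.warn(
                f"skipping candidate {cand.label!r}: K={K} too large for "
                f"n={data.n} data points",
                stacklevel=2,
            )
            continue
        problem = FitProblem(
            data=data,
            family=cand.family,
            n_classes=cand.n_classes,
            structure=config.structure,
            k=config.k,
            prefilters=config.prefilters,
            mode=config.mode,
            include_beta=config.include_beta,
            lambda_bounds=config.lambda_bounds,
            n_starts=n_starts,
            seed=np.random.default_rng([seed, idx]),
            label=cand.label,
        )
        fits.append(fit(problem))
    return selection_table(fits)
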