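"""Exception hierarchy for specsens."""


class SpecsensError(Exception):
    """Base class for all specsens errors."""


class UnsupportedTemplateError(SpecsensError, ValueError):
    """Requested visual-pigment template family is not implemented."""


class CurveError(SpecsensError, ValueError):
    """Invalid spectral curve (non-monotone grid, NaNs, length mismatch...)."""


class CurveParseError(CurveError):
    """A curve file could not be parsed; message carries the offending line."""


class StructuralError(SpecsensError, ValueError):
    """Invalid eye-model structure (no tiers, bad lengths, bad areas...)."""


class DegenerateModelError(SpecsensError, ValueError):
    """Model produced a spectrum that cannot be normalized (all zero)."""


class InfiniteLikelihoodError(SpecsensError, ValueError):
    """RSS of zero gives an unbounded Gaussian likelihood.

    Apply a residual floor (e.g. ``selection.RSS_FLOOR``) or add jitter to
    the data before scoring an exact fit.
    """


class IncompatibleFitsError(SpecsensError, ValueError):
    """Model fits scored on different data cannot share a selection table."""


class InfeasibleProblemError(SpecsensError, ValueError):
    """No feasible starting point exists for the fit problem as posed."""


class ConvergenceError(SpecsensError, RuntimeError):
    """The optimizer failed on every start; diagnostics attached."""
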