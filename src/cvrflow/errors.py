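"""Exception hierarchy for cvrflow.

Invalid-argument conditions raise :class:`ValueError` directly; the classes
here mark conditions that are well-formed inputs but degenerate for the
requested computation, so callers can distinguish them.
"""


class CvrflowError(Exception):
    """Base class for cvrflow-specific errors."""


class EmptyRegionError(CvrflowError):
    """A mask selection produced no voxels."""


class UndefinedCorrelationError(CvrflowError):
    """Correlation requested on a constant (zero-variance) signal."""


class UndefinedFitError(CvrflowError):
    """A regression has a degenerate (constant) regressor."""


class FitFailureError(CvrflowError):
    """Nonlinear peak fit failed to converge after multi-start."""


class UndefinedWidthError(CvrflowError):
    """Peak width requested for a fit with nonpositive amplitude."""


class DegenerateTestError(CvrflowError):
    """Statistical test on zero-variance, nonzero differences."""


class ConfigurationError(CvrflowError):
    """Pipeline configuration inconsistent with the provided inputs."""
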