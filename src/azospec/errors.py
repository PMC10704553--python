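"""Exception hierarchy for azospec.

All azospec-specific failures derive from :class:`AzospecError` so callers
can catch the package's errors without masking programming mistakes.
"""


class AzospecError(Exception):
    """Base class for all azospec errors."""


class InvalidModelError(AzospecError, ValueError):
    """A physical model was constructed with inadmissible parameters."""


class GridError(AzospecError, ValueError):
    """A frequency/time grid is too narrow or too coarse for the request."""


class FormatError(AzospecError, ValueError):
    """A spectrum file does not conform to the expected text dialect."""


class NoBaselineError(AzospecError, ValueError):
    """No flanking baseline region is available for background subtraction."""


class AmbiguousPeakError(AzospecError, ValueError):
    """More than two half-maximum crossings were found.

    Carries the crossing count in :attr:`n_crossings`.
    """

    def __init__(self, message: str, n_crossings: int):
        super().__init__(message)
        self.n_crossings = n_crossings


class OutOfRangeError(AzospecError, ValueError):
    """A width lies outside the admissible order-parameter band."""


class InsufficientBandError(AzospecError, ValueError):
    """Too few usable slices through the 2D band."""


class ContaminatedSliceError(AzospecError, ValueError):
    """The 1->2 band leaks into the 0->1 search window.

    Carries the offending row indices in :attr:`rows`.
    """

    def __init__(self, message: str, rows):
        super().__init__(message)
        self.rows = list(rows)


class UnstableSlopeError(AzospecError, ValueError):
    """The center-line points span too little excitation frequency."""


class DuplicateTimeError(AzospecError, ValueError):
    """Two spectra in a waiting-time series share the same waiting time."""


class FitFailureError(AzospecError, RuntimeError):
    """A nonlinear fit failed to converge after deterministic multistart."""


class EmptyInputError(AzospecError, ValueError):
    """An operation received an empty collection."""


class ConfigError(AzospecError, ValueError):
    """A pipeline configuration is invalid; message lists all violations."""
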