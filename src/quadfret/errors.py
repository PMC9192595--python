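"""Exception hierarchy for the quadfret pipeline."""


class QuadFretError(Exception):
    """Base class for all quadfret errors."""


class FormatError(QuadFretError):
    """A file does not conform to the expected tabular dialect."""


class IntegrityError(QuadFretError):
    """Parsed data violates a structural invariant (e.g. duplicate frames)."""


class ParameterError(QuadFretError, ValueError):
    """An argument is outside its admissible range."""


class EmptyDataError(QuadFretError):
    """An operation received no usable data points."""


class IncompatibleBinsError(QuadFretError):
    """Two histograms do not share identical bin edges."""


class FitError(QuadFretError):
    """A nonlinear fit failed to converge or is non-identifiable.

    Carries the best residual reached, when available, in ``residual``.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual
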