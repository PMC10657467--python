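"""Exception hierarchy for hvprime.

All package-specific errors derive from :class:`HvprimeError` so callers can
catch analysis failures without masking programming errors.
"""


class HvprimeError(Exception):
    """Base class for all hvprime errors."""


class FormatError(HvprimeError):
    """A trace file or its JSON sidecar is missing or malformed."""


class TraceValidationError(HvprimeError, ValueError):
    """A recording, sweep, or sidecar violates a data-model invariant."""


class ParameterError(HvprimeError, ValueError):
    """An argument is outside its documented domain."""


class ProtocolError(HvprimeError):
    """A recording's voltage protocol does not match the requested analysis."""


class FitFailureError(HvprimeError):
    """A nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MethodInapplicableError(HvprimeError):
    """The V-intercept threshold method found no acceptable linear segment."""


class UnreliableCorrectionError(HvprimeError):
    """Rundown correction would divide by a pre-pulse amplitude near the noise floor."""


class DegenerateInputError(HvprimeError):
    """Input data are degenerate for the requested statistic (e.g. zero variance)."""


class InversionError(HvprimeError):
    """A measured value lies outside the invertible range of the model."""


class OutOfRangeError(HvprimeError):
    """A zero crossing (reversal potential) does not occur within the data range."""
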