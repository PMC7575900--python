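"""Exception hierarchy.

All package errors derive from :class:`MRKitError` so callers can catch one
base class; each subclass also derives from ``ValueError`` to behave sensibly
in generic code.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ParameterError(MRKitError, ValueError):
    """A function argument is outside its documented domain."""


class FormatError(MRKitError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(MRKitError, ValueError):
    """A record violates a data-model invariant (reported with row context)."""


class NoOverlapError(MRKitError, ValueError):
    """Exposure and outcome share no SNPs."""


class InsufficientInstrumentsError(MRKitError, ValueError):
    """Too few instruments for the requested estimator."""


class CollinearityError(MRKitError, ValueError):
    """Exposure-beta matrix is rank deficient."""


class DegenerateInputError(MRKitError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. all-zero
    instrument effects, fewer than 10 cases in a simulated cohort)."""
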