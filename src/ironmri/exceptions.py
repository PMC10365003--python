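"""Exception hierarchy.

Everything raised on bad user input derives from :class:`InvalidInputError`
(a ``ValueError``), so callers can catch one type at pipeline boundaries.
"""


class IronMRIError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IronMRIError, ValueError):
    """Input violates a documented precondition (empty mask, bad spec, ...)."""


class InvalidSpecError(InvalidInputError):
    """A simulation spec is inconsistent (overlapping regions, non-PSD copula)."""


class DegenerateFitError(IronMRIError, RuntimeError):
    """Signal does not decay (log-linear slope >= 0); no T2* is defined."""


class InsufficientDataError(InvalidInputError):
    """Too few observations for the requested statistic."""


class EmptyROIError(InvalidInputError):
    """ROI contains no valid pixels."""


class FormatError(IronMRIError, IOError):
    """On-disk data violates the expected format (missing/duplicate TE metadata)."""
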