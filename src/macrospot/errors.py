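"""Exception hierarchy for the macroarray pipeline."""


class MacrospotError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(MacrospotError, ValueError):
    """Array geometry or layout violates a design invariant."""


class GeometryError(MacrospotError, ValueError):
    """An image cannot contain the requested grid."""


class RegistrationError(MacrospotError, RuntimeError):
    """Guide-dot detection or grid fitting failed."""


class DegenerateFitError(RegistrationError):
    """Too few or collinear guide dots: the affine fit is underdetermined."""


class ChannelMismatchError(MacrospotError, ValueError):
    """Channel intersection called with two lists from the same probe format."""


class FormatError(MacrospotError, ValueError):
    """An input file is not in the expected format."""


class InvalidReadingError(MacrospotError, ValueError):
    """A titer reading violates its physical preconditions."""
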