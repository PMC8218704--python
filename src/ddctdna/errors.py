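"""Exception hierarchy for the ddctdna package."""


class DdctdnaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DdctdnaError):
    """A file could not be parsed (missing column, malformed line, ...)."""


class ValidationError(DdctdnaError):
    """An in-memory object violates a domain invariant."""


class SaturationError(DdctdnaError):
    """Every droplet is positive: the Poisson occupancy is unbounded."""


class UndefinedFractionError(DdctdnaError):
    """Allele fraction requested with zero droplets in both channels."""


class NoDetectionError(DdctdnaError):
    """No dilution point (including neat) reached the detection threshold."""
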