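"""Exception hierarchy for data validation and inference failures."""


class SeedShadowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeedShadowError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(SeedShadowError):
    """Record contents violate a domain invariant (e.g. DBH below census cut-off)."""


class ReferentialError(SeedShadowError):
    """A record refers to an entity (trap, species) that does not exist."""


class GeometryError(SeedShadowError):
    """Plot geometry cannot accommodate the requested layout."""


class UnidentifiableError(SeedShadowError):
    """The data carry no information about a parameter (e.g. a species with zero seeds)."""


class InitializationError(SeedShadowError):
    """The sampler could not find a finite starting log-posterior."""


class DiagnosticError(SeedShadowError):
    """Too few draws (or chains) to compute a convergence diagnostic."""
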