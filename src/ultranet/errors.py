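"""Exception hierarchy shared across the package."""


class UltranetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(UltranetError, ValueError):
    """Input violates a contract (asymmetry, non-positive weight, duplicates ...)."""


class FormatError(ValidationError):
    """A file could be read but its contents are malformed."""


class CapabilityError(UltranetError, ValueError):
    """An exhaustive oracle was asked for an instance beyond its size cap."""
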