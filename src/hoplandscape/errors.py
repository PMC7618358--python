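"""Exception hierarchy shared across modules."""


class HopLandscapeError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(HopLandscapeError, ValueError):
    """A simulation or analysis spec violates its invariants."""


class DataIntegrityError(HopLandscapeError, ValueError):
    """Input tables are inconsistent with each other or with a precondition."""


class ConfigurationError(HopLandscapeError, ValueError):
    """A run configuration is malformed or references unknown keys."""
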