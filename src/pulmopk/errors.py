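"""Exception types used across the package."""


class PulmoPKError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PulmoPKError, ValueError):
    """A value violates a documented precondition (nonpositive weight, ...)."""


class ConfigurationError(PulmoPKError, ValueError):
    """A configuration is incomplete or inconsistent (missing ``ka``, unknown
    scaling mode, freeing a parameter the design cannot inform, ...)."""


class EventTableError(PulmoPKError, ValueError):
    """A dataset violates the event-table contract; message carries CSV line
    numbers where applicable."""
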