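"""Exception types shared across the toolkit."""


class CTGError(Exception):
    """Base class for all ctgkit errors."""


class ParseError(CTGError):
    """A record file could not be parsed; the message names the line/field."""


class ConfigurationError(CTGError):
    """Missing or inconsistent configuration (e.g. no sampling rate)."""


class InsufficientDataError(CTGError):
    """The record is too short / too empty for the requested computation."""


class ContractError(CTGError):
    """A caller violated an operation precondition (length mismatch, single
    class, more folds than samples, ...)."""
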