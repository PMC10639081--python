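"""Exception hierarchy shared across the package."""


class IsomutsigError(Exception):
    """Base class for all package-specific errors."""


class ParseError(IsomutsigError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(IsomutsigError):
    """An input violated a documented invariant."""


class ContextUnavailableError(IsomutsigError):
    """The requested reference context runs off the chromosome end."""


class UndefinedSpectrumError(IsomutsigError):
    """A spectrum-valued result is undefined (e.g. an all-zero difference)."""
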