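"""Exception hierarchy shared by every pipeline stage."""


class AleewrError(Exception):
    """Base class for all package errors."""


class InputError(AleewrError, ValueError):
    """Unusable input: missing file, empty training set, bad class layout."""


class ParseError(AleewrError, ValueError):
    """Input file exists but its contents cannot be interpreted."""


class ConfigurationError(AleewrError, ValueError):
    """Required configuration (e.g. a sampling rate) is absent."""


class ParameterError(AleewrError, ValueError):
    """A parameter value violates its stated bound."""


class ShapeError(AleewrError, ValueError):
    """Array dimensions do not match what the operation requires."""


class DegenerateSignalError(AleewrError, ValueError):
    """A signal (or channel) is constant, all-zero, or otherwise degenerate."""


class InvalidRequestError(AleewrError, ValueError):
    """A structurally valid but disallowed request (e.g. drop every component)."""


class SchemeError(AleewrError, ValueError):
    """A cross-validation scheme cannot be realised on the given data."""
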