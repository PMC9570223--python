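"""Exception hierarchy shared across the package."""


class FamsegError(Exception):
    """Base class for all package errors."""


class ParseError(FamsegError):
    """An input file could not be parsed; the message names file and line."""


class ValidationError(FamsegError):
    """Structurally parseable input violated a data contract."""
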