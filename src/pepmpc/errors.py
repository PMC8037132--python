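"""Exception hierarchy shared across the package."""


class PepmpcError(Exception):
    """Base class for package errors."""


class ConfigError(PepmpcError):
    """Invalid configuration value."""


class InvalidSequenceError(PepmpcError):
    """Amino-acid sequence contains a letter outside the 20 standard codes."""


class ParseError(PepmpcError):
    """Malformed structure or trajectory file.

    Attributes
    ----------
    path : str | None
    line : int | None
        1-based line number of the offending record, when known.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
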