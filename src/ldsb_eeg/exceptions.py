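"""Exception hierarchy used across the package."""


class LdsbEegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LdsbEegError, ValueError):
    """An argument violates an operation's contract."""


class DegenerateInputError(LdsbEegError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. constant)."""


class FormatError(LdsbEegError, IOError):
    """A file exists but cannot be parsed under the requested dialect."""
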