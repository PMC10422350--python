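"""Exception hierarchy shared by all lungsig modules."""


class LungsigError(Exception):
    """Base class for all lungsig errors."""


class ConfigurationError(LungsigError, ValueError):
    """A parameter violates a module contract (bad cutoff, window, seed ...)."""


class FormatError(LungsigError, ValueError):
    """A structurally invalid input file (missing column, length mismatch ...)."""


class ParseError(LungsigError, ValueError):
    """An unreadable input file; the message names the offending line where known."""
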