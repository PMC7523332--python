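"""Exception hierarchy shared across the package."""


class TmescopeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TmescopeError):
    """An on-disk artifact is missing or malformed."""


class ValidationError(TmescopeError, ValueError):
    """An in-memory object violates a documented contract."""


class ConfigError(TmescopeError, ValueError):
    """A simulation or pipeline configuration is invalid."""
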