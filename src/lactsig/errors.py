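"""Exception types shared across the package."""


class LactsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LactsigError, ValueError):
    """An on-disk artifact violates its format contract."""


class JoinError(LactsigError, ValueError):
    """Two tables that must cover identical keys do not."""


class ConfigError(LactsigError, ValueError):
    """A simulation or pipeline configuration is invalid."""
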