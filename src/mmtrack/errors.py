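"""Exception hierarchy shared across the package."""


class MMTError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MMTError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(MMTError, ValueError):
    """A file does not follow the documented dialect; message names the line."""


class SingularityError(MMTError, ValueError):
    """A field evaluation was requested at (or too close to) the source."""


class GeometryError(MMTError, ValueError):
    """Phantom/sphere geometry is physically infeasible."""


class ConfigError(MMTError, ValueError):
    """A run configuration is missing, malformed, or inconsistent."""
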