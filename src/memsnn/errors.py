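"""Exception types shared across the package."""


class MemsnnError(Exception):
    """Base class for all package-specific errors."""


class RangeError(MemsnnError, ValueError):
    """A scalar or array argument lies outside its documented domain."""


class ShapeError(MemsnnError, ValueError):
    """An array argument has the wrong shape."""


class FormatError(MemsnnError, ValueError):
    """A file does not follow the expected on-disk format."""


class FittingError(MemsnnError, ValueError):
    """Parameter estimation received degenerate or inconsistent data."""


class ConfigError(MemsnnError, ValueError):
    """A configuration file or override contains invalid entries."""
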