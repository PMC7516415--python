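"""Exception types shared across the pipeline."""


class ScanpathError(Exception):
    """Base class for all package errors."""


class ConfigError(ScanpathError):
    """A configuration file or schema is missing something it must declare."""


class ValidationError(ScanpathError):
    """Input data violate an invariant (timing, ordering, probability mass)."""


class GeometryError(ScanpathError):
    """An AOI polygon is degenerate or self-intersecting."""


class AmbiguityError(ScanpathError):
    """A reducible chain has several closed classes; no unique stationary law."""
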