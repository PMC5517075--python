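"""Exception hierarchy.

Everything raised on bad inputs derives from :class:`TracheoQuantError` so
callers (and the CLI) can catch one base class.
"""


class TracheoQuantError(Exception):
    """Base class for all package errors."""


class ParameterError(TracheoQuantError, ValueError):
    """Invalid parameter values (violated invariants)."""


class GeometryError(TracheoQuantError, ValueError):
    """Objects that do not fit or overlap where they must not."""


class PlacementError(TracheoQuantError, RuntimeError):
    """Random placement failed after bounded retries (field too crowded)."""


class FormatError(TracheoQuantError, ValueError):
    """Unreadable or schema-violating file content."""


class MeasurementError(TracheoQuantError, ValueError):
    """A measurement is undefined for the given input (empty region,
    point outside mask, zero denominator)."""


class TracingError(TracheoQuantError, RuntimeError):
    """Automatic centerline tracing failed (blank image, disconnected
    skeleton)."""


class ConfigError(TracheoQuantError, ValueError):
    """Pipeline configuration does not validate."""
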