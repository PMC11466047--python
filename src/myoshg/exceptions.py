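"""Typed errors raised across the package.

All inherit from :class:`MyoshgError` so callers can catch broadly; the
subclasses distinguish bad parameters, bad geometry, undefined metrics,
placement failures in the synthetic generator, and unsupported file formats.
"""


class MyoshgError(Exception):
    """Base class for all package errors."""


class ParameterError(MyoshgError, ValueError):
    """A parameter violates a stated invariant; the message names it."""


class GeometryError(MyoshgError, ValueError):
    """A geometric construction (line, ROI) exits the image bounds."""


class UndefinedMetricError(MyoshgError, ZeroDivisionError):
    """A metric is mathematically undefined for this input (e.g. zero
    cardiomyocyte area); never silently coerced to 0 or infinity."""


class PlacementError(MyoshgError, RuntimeError):
    """Dart-throwing placement budget exhausted; lower object density."""


class FormatError(MyoshgError, ValueError):
    """Unsupported file format or pixel type; the message names it."""
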