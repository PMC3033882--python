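"""Exception hierarchy.

All surfmorph errors derive from :class:`SurfmorphError` so callers can
catch the package's failures with a single clause.
"""


class SurfmorphError(Exception):
    """Base class for all surfmorph errors."""


class FormatError(SurfmorphError):
    """A file is not in the expected on-disk format (bad magic, wrong kind)."""


class ParseError(SurfmorphError):
    """A file in the right format is truncated or malformed."""


class ConsistencyError(SurfmorphError):
    """Inputs that must agree (vertex counts, measure names, subjects) do not."""


class GeometryError(SurfmorphError):
    """A mesh violates a geometric precondition (degenerate surface, bad face)."""


class CalibrationError(SurfmorphError):
    """Smoothing calibration cannot reach the requested kernel width."""


class ConfigError(SurfmorphError):
    """A pipeline configuration is missing or names a nonexistent input."""


class LocalizationError(SurfmorphError):
    """An electrode position is too far from the surface to snap to it."""
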