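"""Exception hierarchy for the keratrace pipeline.

All package-raised errors derive from :class:`KeratraceError` so the CLI can
map any data-level failure onto a nonzero exit code with a one-line cause.
"""


class KeratraceError(Exception):
    """Base class for all keratrace errors."""


class DomainError(KeratraceError, ValueError):
    """A geometric or numeric argument lies outside its valid domain."""


class NoIntersectionError(KeratraceError):
    """A ray misses a surface within its valid aperture."""


class TotalInternalReflectionError(KeratraceError):
    """Snell refraction has a negative discriminant (ray cannot pass)."""


class InsufficientCoverageError(KeratraceError):
    """Too many missing samples under a ring/zone aggregation request."""


class ReshapeError(KeratraceError):
    """Surgical reshape would produce a non-physical cornea."""


class SchemaError(KeratraceError):
    """An input table does not match the cohort schema."""


class ConfigError(KeratraceError):
    """A run configuration file is invalid."""
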