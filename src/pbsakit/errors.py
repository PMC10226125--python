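"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`PbsakitError`
so the CLI can map any library failure onto a single-line diagnostic and a
nonzero exit code.
"""


class PbsakitError(Exception):
    """Base class for all errors raised by pbsakit."""


class FormatError(PbsakitError):
    """A file could not be parsed (message names the offending line/row)."""


class EmptyInputError(PbsakitError):
    """An input contained no usable records."""


class LookupTableError(PbsakitError):
    """A required table entry (e.g. a vdW radius) is missing."""


class GeometryError(PbsakitError):
    """Sampling-cell or structure geometry is inconsistent."""


class ResolutionError(PbsakitError):
    """A lattice resolution is too coarse for the structure."""


class SchemaError(PbsakitError):
    """A term table is missing mandatory columns."""


class IntegrityError(PbsakitError):
    """A record set violates an internal consistency requirement."""


class ConfigError(PbsakitError):
    """A model/regime configuration is incomplete or contradictory."""


class SingularDesignError(PbsakitError):
    """The fit design matrix is rank deficient."""


class MetricError(PbsakitError):
    """A statistic is undefined for the given inputs."""


class GenerationError(PbsakitError):
    """A synthetic-data generator could not satisfy its constraints."""
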