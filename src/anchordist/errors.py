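"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`AnchordistError`, with a machine-readable ``category`` used by the
command-line layer for single-line error reporting.
"""


class AnchordistError(Exception):
    """Base class for all anchordist errors."""

    category = "error"


class SchemaError(AnchordistError):
    """A required column or field is missing or malformed."""

    category = "schema"


class ParseError(AnchordistError):
    """A value could not be parsed (carries a row number where known)."""

    category = "parse"


class DimensionalityError(AnchordistError):
    """2D/3D inconsistency: some cells carry a z coordinate, others do not."""

    category = "dimensionality"


class ValidationError(AnchordistError):
    """An invariant on a domain object is violated."""

    category = "validation"


class ConsistencyError(AnchordistError):
    """Cross-table references do not resolve (e.g. dangling cell ids)."""

    category = "consistency"


class MappingError(AnchordistError):
    """A label mapping is missing entries it is required to cover."""

    category = "mapping"


class SizeError(AnchordistError):
    """An operation was asked for more items than the data contains."""

    category = "size"


class InsufficientDataError(AnchordistError):
    """Too few observations/replicates for the requested statistic."""

    category = "insufficient-data"


class PairingError(AnchordistError):
    """A paired design is incomplete for at least one donor."""

    category = "pairing"


class DegenerateDesignError(AnchordistError):
    """A regression design is degenerate (e.g. constant covariate)."""

    category = "degenerate-design"


class ConfigError(AnchordistError):
    """A simulation or pipeline configuration is invalid."""

    category = "config"
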