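"""Exception hierarchy shared across the package."""


class SnpMetaError(Exception):
    """Base class for all package errors."""


class SchemaError(SnpMetaError):
    """The study table is missing a required column or has a malformed header."""


class ValidationError(SnpMetaError):
    """A study row violates an invariant (negative count, duplicate id, ...)."""


class DegenerateTableError(SnpMetaError):
    """A 2x2 table has an empty case or control margin and carries no information."""


class PoolingError(SnpMetaError):
    """Pooling was requested on an empty or wholly degenerate set of studies."""


class HeterogeneityUndefinedError(SnpMetaError):
    """Cochran's Q needs at least two studies."""


class InsufficientStudiesError(SnpMetaError):
    """A publication-bias test needs at least three studies."""


class DegenerateCovariateError(SnpMetaError):
    """Meta-regression covariate has a single level."""


class ConfigError(SnpMetaError):
    """A simulation or analysis configuration is invalid."""
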