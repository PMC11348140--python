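"""Exception types shared across the package."""


class SynfacError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(SynfacError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSeriesError(SynfacError, ValueError):
    """A time series has zero variance (or is otherwise unusable)."""


class SingularCovarianceError(SynfacError, ValueError):
    """A covariance block is singular; usually a duplicated region."""


class InternalInconsistencyError(SynfacError, RuntimeError):
    """A constraint system that should always be solvable was not."""


class CollinearityError(SynfacError, ValueError):
    """A design matrix is rank deficient."""

    def __init__(self, msg, columns=()):
        super().__init__(msg)
        self.columns = list(columns)


class InsufficientSampleError(SynfacError, ValueError):
    """Too few subjects for the requested statistic."""


class SchemaError(SynfacError, ValueError):
    """Tables or vectors do not line up (lengths, labels, regions)."""


class MissingDataError(SynfacError, ValueError):
    """Required per-subject values are missing."""

    def __init__(self, msg, subjects=()):
        super().__init__(msg)
        self.subjects = list(subjects)


class DegenerateNormalizationError(SynfacError, ValueError):
    """A control-group entry has zero spread, so z-scoring is undefined."""


class UndefinedCorrelationError(SynfacError, ValueError):
    """A correlation of a constant vector was requested."""


class CannotMatchVariogramError(SynfacError, ValueError):
    """The distance structure does not admit variogram matching."""


class DivergenceError(SynfacError, RuntimeError):
    """A numerical integration produced non-finite state."""

    def __init__(self, msg, time=None, region=None):
        super().__init__(msg)
        self.time = time
        self.region = region


class FittingFailedError(SynfacError, RuntimeError):
    """An optimizer failed to produce any finite candidate."""


class ConfigError(SynfacError, ValueError):
    """A run configuration is malformed."""
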