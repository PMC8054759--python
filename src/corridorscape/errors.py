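"""Domain-specific error types shared across the pipeline stages."""


class SchemaError(ValueError):
    """A table is missing required columns or has malformed rows."""


class MissingLayerError(KeyError):
    """A raster stack lacks a layer the operation requires."""


class DegenerateWeightsError(ValueError):
    """All sampling or ensemble weights are zero/non-positive."""


class InsufficientBackgroundError(ValueError):
    """Fewer valid background cells than requested pseudo-absences."""


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined because a layer has zero variance."""


class ConfigurationError(ValueError):
    """A run configuration is inconsistent or incomplete."""


class EmptyDesignError(ValueError):
    """No usable presence rows remain after extraction."""


class DegenerateDesignError(ValueError):
    """The design matrix is singular or single-class."""


class DegenerateRangeError(ValueError):
    """A raster is constant where a spread of values is required."""


class EmptyGraphError(ValueError):
    """Every cell of the conductance raster is masked."""


class NoPathError(ValueError):
    """Destination unreachable from source on the conductance graph."""


class NoPathsError(ValueError):
    """No (winter, summer) endpoint pair produced a least-cost path."""


class SingularSystemError(ValueError):
    """Sources and grounds are not connected; the circuit system is singular."""


class UndefinedStatisticError(ValueError):
    """A spatial statistic is undefined (e.g. zero variance)."""
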