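"""Exception types shared across the package."""


class SpatproxError(Exception):
    """Base class for all package errors."""


class FormatError(SpatproxError):
    """An input file does not match the expected layout (e.g. a missing column)."""


class EmptyInputError(SpatproxError):
    """No usable records remain after cleaning."""


class ValidationError(SpatproxError):
    """A value violates a declared invariant or vocabulary."""


class UndefinedMetricError(SpatproxError):
    """A spatial metric is undefined (e.g. no central cells); callers should
    propagate a missing value, never 0."""


class UndefinedTestError(SpatproxError):
    """A statistical test is undefined for the given input (e.g. a zero margin,
    an all-missing group, or constant values for a correlation)."""
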