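"""Exception hierarchy.

Every error the pipeline raises derives from :class:`NicheCmpError`, so callers
(and the CLI) can catch one type and report a stage-tagged message.
"""


class NicheCmpError(Exception):
    """Base class for all package errors."""


class ArgumentError(NicheCmpError, ValueError):
    """Invalid argument value (bad dimensions, out-of-range parameter, ...)."""


class GeometryError(NicheCmpError):
    """Region masks would overlap, be empty, or not fit on the grid."""


class SamplingError(NicheCmpError):
    """Not enough eligible cells to draw the requested sample."""


class SchemaError(NicheCmpError):
    """Input file or layer set does not match the expected schema."""


class ValidationError(NicheCmpError):
    """Records fail validation (e.g. coordinates off-grid); lists offenders."""


class AlignmentError(NicheCmpError):
    """Grids or surfaces that must be cell-aligned are not."""


class NormalizationError(NicheCmpError):
    """A surface that must sum to one does not."""


class BandwidthError(NicheCmpError):
    """Kernel bandwidth degenerated to zero; set an explicit floor bandwidth."""


class DegenerateInputError(NicheCmpError):
    """Input is degenerate for the requested fit (zero variance, rank loss)."""


class SupportError(NicheCmpError):
    """Background support too small to admit the requested randomization."""


class EmptyConsensusError(NicheCmpError):
    """No replicate map passed the TSS acceptance cutoff."""


class UndefinedStatisticError(NicheCmpError):
    """A confusion-table margin is empty; the statistic is undefined."""
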