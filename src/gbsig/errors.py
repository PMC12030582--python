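"""Exception hierarchy shared across the pipeline."""


class GbsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GbsigError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(GbsigError, ValueError):
    """An input file does not conform to the expected dialect."""


class UsageError(GbsigError, ValueError):
    """An operation was called with arguments that make no sense."""


class UndefinedStatisticError(GbsigError, ValueError):
    """A disproportionality statistic is undefined for the given table
    (zero cell or zero margin) and no continuity correction was requested."""


class InversionError(GbsigError, RuntimeError):
    """Contingency-table inversion failed to reach the residual tolerance."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class NoInstrumentsError(GbsigError, ValueError):
    """No SNP survived instrument selection for a protein."""
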