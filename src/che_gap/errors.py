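"""Exception hierarchy shared across the pipeline stages."""


class CheGapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CheGapError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(CheGapError):
    """Input data violate a precondition (e.g. OOP spending above total)."""


class SchemaError(CheGapError):
    """A record carries an unknown categorical level or a missing required column."""


class DegenerateCutoffError(CheGapError):
    """Too few distinct values to form the requested number of quantile groups."""

    def __init__(self, variable: str, wave, k: int, n_distinct: int):
        self.variable = variable
        self.wave = wave
        self.k = k
        self.n_distinct = n_distinct
        super().__init__(
            f"cannot form {k} groups for {variable!r} in wave {wave}: "
            f"only {n_distinct} distinct value(s)"
        )


class EstimationError(CheGapError):
    """A normative-spending window selected no households."""


class PipelineOrderError(CheGapError):
    """A stage was invoked before the stage that produces its inputs."""


class ModelInfeasibleError(CheGapError):
    """A regression model cannot be fitted (empty table, single-level outcome...)."""
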