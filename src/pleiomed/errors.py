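"""Exception hierarchy shared across the package."""


class PleiomedError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PleiomedError, ValueError):
    """An invalid simulation or pipeline configuration."""


class DataError(PleiomedError, ValueError):
    """Input data violate a precondition (bad alleles, empty counts, ...)."""


class DegenerateDesignError(PleiomedError, ValueError):
    """A regression design is degenerate: constant exposure, single-class
    outcome, perfect separation, or fewer observations than parameters."""


class MonomorphicError(DataError):
    """Hardy-Weinberg test requested for a SNP with only one allele."""


class NullTotalEffectError(PleiomedError, ValueError):
    """Proportion mediated is undefined because the total effect is null."""


class PipelineError(PleiomedError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
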