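"""Exception hierarchy for the MR pipeline."""


class MrKitError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MrKitError):
    """A run or column configuration is unusable (missing column, bad path)."""


class ValidationError(MrKitError):
    """Input data violates a record invariant (non-positive se, duplicate id, ...)."""


class EstimationError(MrKitError):
    """An estimator's preconditions are not met (too few SNPs, degenerate instrument)."""
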