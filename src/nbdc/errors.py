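"""Exception hierarchy shared across the pipeline."""


class NBDCError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(NBDCError):
    """A configuration value violates its contract."""


class ValidationError(NBDCError):
    """Input data failed schema or range validation."""


class ContractViolation(NBDCError):
    """An operation was called outside its stated precondition."""
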