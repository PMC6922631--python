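"""Exception types shared across the package."""


class TopoprofileError(ValueError):
    """Base class for domain errors."""


class SchemaError(TopoprofileError):
    """A table or config is missing required columns/keys."""


class DataError(TopoprofileError):
    """Input values violate a contract (duplicates, zero variance, ...)."""
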