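"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A tabular input is missing required columns or has malformed values."""


class DegenerateDataError(ValueError):
    """Data are too sparse or too degenerate for the requested estimate."""


class IncompleteDesignError(ValueError):
    """A repeated-measures table is missing cells for some participant."""


class InconsistentFitsError(ValueError):
    """Nested model fits violate the required likelihood ordering."""


class ConfigError(ValueError):
    """A study configuration is invalid; the message lists every violation."""
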