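"""Exception types shared across the package."""


class CellageError(ValueError):
    """Base class for all validation and pipeline errors."""


class ConfigError(CellageError):
    """A configuration violates one of its documented constraints."""
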