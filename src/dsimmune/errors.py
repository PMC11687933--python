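"""Exception hierarchy for the dsimmune pipeline."""


class DsimmuneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DsimmuneError):
    """A configuration value is outside its permitted range or malformed."""


class SchemaError(DsimmuneError):
    """A table does not conform to its declared schema."""


class DegenerateSampleError(DsimmuneError):
    """A sample has zero spread and cannot be MAD-standardized."""


class AssayInvalidError(DsimmuneError):
    """A scalar assay's controls are inconsistent (e.g. positive <= negative)."""
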