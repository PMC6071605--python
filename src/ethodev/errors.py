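"""Exception types shared across the pipeline stages."""


class EthodevError(Exception):
    """Base class for all package errors."""


class ConfigError(EthodevError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(EthodevError):
    """Input table is missing required columns or terms."""


class DataError(EthodevError):
    """Input values violate a precondition (e.g. more adults than eggs)."""


class InsufficientReplicationError(EthodevError):
    """Fewer than two replicates per cell; variance partitioning undefined."""
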