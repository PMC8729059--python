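"""Package-level error types, mapped to CLI exit codes (config=2, data=3)."""


class CytoscreenError(Exception):
    """Base class for package errors."""


class ConfigError(CytoscreenError):
    """Invalid configuration: bad schema, unknown keys, out-of-range values."""


class DataError(CytoscreenError):
    """Invalid or missing input data."""
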