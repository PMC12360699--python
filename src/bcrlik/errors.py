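"""Exception hierarchy shared across the pipeline."""


class BcrlikError(Exception):
    """Base class for package errors."""


class ConfigError(BcrlikError):
    """Invalid configuration (bad parameter values, malformed YAML, ...)."""


class DataError(BcrlikError):
    """Invalid or inconsistent input data (missing columns, empty repertoire, ...)."""
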