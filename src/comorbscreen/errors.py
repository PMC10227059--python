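"""Exception types shared across the pipeline.

ConfigError maps to CLI exit code 1, DataError to exit code 2.
"""


class ComorbScreenError(Exception):
    """Base class for package errors."""


class ConfigError(ComorbScreenError, ValueError):
    """Invalid configuration (bad thresholds, impossible prevalence, ...)."""


class DataError(ComorbScreenError, ValueError):
    """Invalid or inconsistent input data (schema, malformed codes, ...)."""
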