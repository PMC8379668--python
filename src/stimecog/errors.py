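"""Exception hierarchy.

Config problems, malformed input data, and insufficient-data conditions are
distinguished so the command-line layer can map them to distinct exit codes.
"""


class StimEcogError(Exception):
    """Base class for all package errors."""


class ConfigError(StimEcogError, ValueError):
    """Invalid parameter or configuration value."""


class SchemaError(StimEcogError, ValueError):
    """Input table/file does not match the documented schema."""


class UnsupportedFormatError(StimEcogError, ValueError):
    """File extension or dialect not recognised."""


class DataError(StimEcogError):
    """Input data present but unusable for the requested operation."""


class InsufficientDataError(DataError):
    """Too few valid samples, trials, or pairs for the requested statistic."""
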