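"""Exception hierarchy shared across the package.

``ValidationError`` covers bad parameters and configuration (CLI exit code 2);
``DataError`` covers inputs that are structurally valid but unusable, such as
recordings that are too short or constant channels (CLI exit code 3).
"""


class EnvtailsError(Exception):
    """Base class for all package errors."""


class ValidationError(EnvtailsError):
    """A parameter or configuration value violates its contract."""


class DataError(EnvtailsError):
    """Input data cannot support the requested operation."""
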