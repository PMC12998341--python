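"""Exception hierarchy.

Exit-code mapping in the CLI relies on this split: configuration problems,
input-schema problems, and computation/linkage problems are distinct failure
classes for callers running the pipeline unattended.
"""


class ClaimsBirthError(Exception):
    """Base class for all package errors."""


class ConfigError(ClaimsBirthError):
    """Malformed code-set or generator configuration."""


class SchemaError(ClaimsBirthError):
    """An input table violates its declared schema."""


class LinkageError(ClaimsBirthError):
    """Referential problem in the parent-child link table."""


class UnsupportedOracleError(ClaimsBirthError):
    """The closed-form sensitivity oracle does not cover this configuration."""
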