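"""Exception hierarchy for the pipeline.

All errors raised by the package derive from :class:`SecretomeError` so callers
can catch one base class; the subclasses mirror the three failure modes of a
file-driven pipeline (malformed input, internally inconsistent input, misuse of
an operation) plus configuration problems.
"""


class SecretomeError(Exception):
    """Base class for all package errors."""


class FormatError(SecretomeError):
    """A file does not conform to its documented dialect."""


class IntegrityError(SecretomeError):
    """Inputs are parseable but mutually inconsistent (broken joins, duplicates)."""


class UsageError(SecretomeError):
    """An operation was called with arguments outside its contract."""


class ConfigError(SecretomeError):
    """A configuration value is invalid or infeasible."""
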