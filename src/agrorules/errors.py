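"""Exception hierarchy shared across the pipeline.

``AgroRulesError`` is the common base so callers (notably the CLI) can map any
library failure onto a data-error exit code without enumerating subclasses.
"""


class AgroRulesError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(AgroRulesError):
    """A required attribute, zone, or setting is missing or inconsistent."""


class InvalidTableError(AgroRulesError):
    """A threshold table violates low_cut <= high_cut or its schema."""


class MissingValueError(AgroRulesError):
    """A value that must be numeric is NaN or unparseable."""


class JoinError(AgroRulesError):
    """A (zone, year) key needed for a join has no match."""

    def __init__(self, missing_keys):
        self.missing_keys = list(missing_keys)
        super().__init__(f"no annual yield for keys: {self.missing_keys}")


class InfeasibleRuleError(AgroRulesError):
    """A planted-rule specification cannot be realised on the given data."""


class EmptyInputError(AgroRulesError):
    """An operation that needs at least one record/transaction got none."""


class OracleRefusedError(AgroRulesError):
    """The brute-force enumerator declined an input too large to enumerate."""
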