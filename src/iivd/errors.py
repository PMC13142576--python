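"""Exception hierarchy.

``ValidationError`` subclasses map to CLI exit code 1 (bad inputs or
configuration); everything else raised by the library maps to exit code 2.
"""


class IIVDError(Exception):
    """Base class for all library errors."""


class ValidationError(IIVDError):
    """Invalid user input: schema violations, bad configuration values."""


class SchemaError(ValidationError):
    """A cohort table violates the documented column schema."""


class UndefinedDispersionError(IIVDError):
    """CoV requested for a panel whose mean composite is not positive."""


class DegenerateStatisticError(IIVDError):
    """A test statistic is undefined (zero variance, zero margin, ...)."""


class SeparationError(IIVDError):
    """Logistic likelihood is unbounded (complete or quasi-separation)."""


class UnstageableError(IIVDError):
    """A record lacks the biomarker flags needed for stage assignment."""
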