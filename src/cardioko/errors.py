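"""Exception hierarchy.

Validation failures (bad configuration, malformed files, unknown vocabulary
tokens) and data failures (referential breakage, degenerate statistics) are
kept distinct so the CLI can map them onto exit codes 2 and 3 respectively.
"""


class CardiokoError(Exception):
    """Base class for all package errors."""


class ValidationError(CardiokoError):
    """A problem the user can fix by correcting configuration or input files."""


class ConfigError(ValidationError):
    """Invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SchemaError(ValidationError):
    """Input file does not match the expected column schema."""


class VocabularyError(ValidationError):
    """A token outside a controlled vocabulary (rating, consequence, ...)."""


class DataError(CardiokoError):
    """Inputs are well-formed but the requested computation is impossible."""


class ReferentialError(DataError):
    """A record refers to an entity (e.g. ontology term) that does not exist."""


class InsufficientDataError(DataError):
    """Not enough observations to make a call (e.g. litter below min_pups)."""


class UndefinedStatisticError(DataError):
    """The requested statistic is undefined for this input (e.g. OR with a
    double-zero diagonal, or a similarity score with no informative terms)."""
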