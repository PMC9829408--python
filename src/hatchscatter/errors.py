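"""Exception hierarchy for hatchscatter.

All user-facing failures derive from :class:`HatchscatterError` so the CLI can
map library errors to exit code 1 while argument-parsing problems stay exit 2.
"""


class HatchscatterError(Exception):
    """Base class for all hatchscatter errors."""


class InputSchemaError(HatchscatterError, ValueError):
    """A required column is missing or the input table is malformed."""


class CoordinateParseError(HatchscatterError, ValueError):
    """A coordinate value failed to parse as a finite number."""


class EmptyInputError(HatchscatterError, ValueError):
    """The input table contains no records."""


class UnknownIdError(HatchscatterError, KeyError):
    """A referenced point id does not exist in the table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class ParameterError(HatchscatterError, ValueError):
    """A numeric parameter is outside its valid domain."""


class PatternNameError(HatchscatterError, ValueError):
    """An unknown named pattern was requested."""


class CapacityError(HatchscatterError, ValueError):
    """More groups than distinct (color, pattern) combinations available."""


class MappingError(HatchscatterError, KeyError):
    """A group present in the data has no aesthetic assignment."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class FormatError(HatchscatterError, ValueError):
    """An unsupported output format was requested."""
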