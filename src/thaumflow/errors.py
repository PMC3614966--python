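"""Exception hierarchy shared across the package."""


class ThaumflowError(Exception):
    """Base class for all package errors."""


class ValidationError(ThaumflowError, ValueError):
    """Input fails a structural or range constraint."""


class InvalidAlphabetError(ValidationError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""

    def __init__(self, char: str, position: int | None = None, context: str = ""):
        self.char = char
        self.position = position
        where = f" at position {position}" if position is not None else ""
        ctx = f" in {context}" if context else ""
        super().__init__(f"invalid nucleotide character {char!r}{where}{ctx}")


class InputSizeError(ValidationError):
    """An input is too short/small for the requested operation."""


class PatternParseError(ValidationError):
    """A mismatch-pattern string cannot be parsed against its primer."""


class InconsistentPatternError(ValidationError):
    """A pattern token claims a mismatch with a base the primer tolerates."""


class MissingTipError(ValidationError):
    """OTUs present in a count table are absent from the community tree."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"OTUs missing from tree: {', '.join(self.missing)}")
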