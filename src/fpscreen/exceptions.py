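"""Exception hierarchy shared across fpscreen modules."""


class FpscreenError(Exception):
    """Base class for all fpscreen errors."""


class ParseError(FpscreenError):
    """A fingerprint file row could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DimensionError(FpscreenError):
    """Feature dimensions of two objects do not agree."""


class DegenerateInputError(FpscreenError):
    """A similarity score is undefined for the given pair (e.g. both empty)."""
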