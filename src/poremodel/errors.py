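"""Exception hierarchy.

Format errors (exit code 3 in the CLI) are distinguished from empty-result
conditions (exit code 4) so scripted pipelines can react differently.
"""


class PoremodelError(Exception):
    """Base class for all package errors."""


class FormatError(PoremodelError):
    """Malformed input: bad ss string, ragged model table, missing header."""


class SsParseError(FormatError):
    """ss operation string does not match the grammar.

    Carries ``offset``, the byte offset of the offending token.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


class BoundsError(PoremodelError):
    """Alignment cursor ran past the end of the signal or the sequence."""


class DegenerateSignalError(PoremodelError):
    """Signal has zero spread (MAD = 0); normalization is undefined."""


class EmptyResultError(PoremodelError):
    """A pipeline stage produced nothing (e.g. zero aligned events)."""
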