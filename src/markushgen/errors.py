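"""Exception hierarchy for the Markush drafting pipeline."""


class MarkushError(Exception):
    """Base class for all package errors."""


class MissingInput(MarkushError):
    """An input file is absent, unreadable, or contains no records."""


class ParseError(MarkushError):
    """A chemical record could not be parsed or sanitized."""


class InputTooSmall(MarkushError):
    """Fewer molecules than the operation requires (core finding needs >= 2)."""


class NoCommonCore(MarkushError):
    """The series shares no connected substructure large enough to act as a core."""


class CoreMismatch(MarkushError):
    """A molecule does not contain the core/scaffold as a substructure."""


class BridgingFragmentWarning(UserWarning):
    """A harvested fragment bonds to two or more core atoms (divalent linker)."""


class InvalidArgument(MarkushError):
    """An argument violates an operation precondition (e.g. k <= 0)."""


class Unsupported(MarkushError):
    """The operation does not support this input (e.g. multi-attachment term generation)."""


class ValidationError(MarkushError):
    """A document or claim object fails its structural invariants."""
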