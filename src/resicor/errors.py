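"""Exception hierarchy.

All package-raised errors derive from :class:`ResicorError`; the value-like
subclasses also derive from :class:`ValueError` so they behave sensibly inside
numpy/sklearn call stacks.
"""


class ResicorError(Exception):
    """Base class for all errors raised by resicor."""


class ParseError(ResicorError, ValueError):
    """A file could not be parsed; the message names the offending row/column."""


class DomainError(ResicorError, ValueError):
    """An input violates a mathematical precondition (length, sign, variance)."""


class StructuralError(ResicorError, ValueError):
    """Multiple inputs that must agree structurally do not (e.g. residue sets)."""


class BudgetExceededError(ResicorError):
    """An enumeration would exceed the configured budget."""


class PipelineError(ResicorError):
    """The end-to-end pipeline cannot proceed (e.g. empty selection)."""
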