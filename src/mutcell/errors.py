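"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2 (bad input / bad configuration),
every other ``MutcellError`` to exit code 1.
"""


class MutcellError(Exception):
    """Base class for all package errors."""


class FormatError(MutcellError):
    """A file does not conform to its declared format."""


class ValidationError(MutcellError):
    """Input data violates a documented precondition or invariant."""


class ConvergenceError(MutcellError):
    """An iterative fit failed to converge."""
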