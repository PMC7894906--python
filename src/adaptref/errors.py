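"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 1, :class:`DataError`
-> 2, :class:`NumericalError` -> 3.
"""


class AdaptrefError(Exception):
    """Base class for all package errors."""


class DataError(AdaptrefError, ValueError):
    """Invalid, missing, or inconsistent input data."""


class NumericalError(AdaptrefError, RuntimeError):
    """A numerical procedure failed (degenerate variance, no draws, ...)."""
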