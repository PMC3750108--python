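"""Exception hierarchy shared across the package.

Everything user-facing derives from :class:`PLPError` so the command-line
layer can catch one type and exit with a one-line diagnostic.
"""


class PLPError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PLPError, ValueError):
    """A file does not conform to its documented text format."""


class ValidationError(PLPError, ValueError):
    """Inputs are well-formed but violate a model invariant."""


class AlignmentError(PLPError, ValueError):
    """Row/column labels of two inputs do not line up."""


class ConvergenceError(PLPError, RuntimeError):
    """An iterative routine failed to converge within its iteration budget."""


class ResourceLimitError(PLPError, RuntimeError):
    """A combinatorial computation exceeded its configured size cap."""
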