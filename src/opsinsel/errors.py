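"""Exception types shared across the package.

The CLI maps these onto exit codes: validation problems exit 2,
optimizer non-convergence exits 3.
"""


class OpsinselError(Exception):
    """Base class for package errors."""


class FormatError(OpsinselError):
    """A file could not be parsed in its declared format."""


class ValidationError(OpsinselError):
    """Parsed input violates an invariant (lengths, stops, names...)."""


class UnsupportedTreeError(ValidationError):
    """Tree too small or otherwise outside the supported shapes."""


class ConvergenceError(OpsinselError):
    """Optimization failed to converge after all starting points."""


class EstimationError(OpsinselError):
    """A quantity could not be estimated from the data given."""
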