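"""Exception hierarchy.

Validation problems (bad parameter values, malformed input files,
uninformative curves) raise :class:`ValidationError`; optimiser failures
raise :class:`FitConvergenceError`.  The CLI maps these to exit codes 2
and 3 respectively.
"""


class RelkinError(Exception):
    """Base class for all package errors."""


class ValidationError(RelkinError, ValueError):
    """Input or parameter outside its physical/contractual domain."""


class UninformativeCurveError(ValidationError):
    """A release curve with no non-trivial points left after filtering."""


class FitConvergenceError(RelkinError, RuntimeError):
    """All optimisation starts failed to converge."""
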