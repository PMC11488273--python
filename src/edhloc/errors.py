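"""Exception hierarchy.

Validation failures (bad inputs, infeasible configuration) are distinguished
from numerical convergence failures so callers — and the CLI exit codes — can
tell user error from optimizer trouble.
"""


class EdhlocError(Exception):
    """Base class for package errors."""


class ValidationError(EdhlocError, ValueError):
    """Invalid input data or configuration."""


class DegenerateDataError(ValidationError):
    """Data admits no meaningful estimate (e.g. zero total variance)."""


class ConvergenceError(EdhlocError, RuntimeError):
    """An iterative fit failed to converge; message carries the trace."""
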