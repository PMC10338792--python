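"""Exception hierarchy for eventdfa.

All errors derive from :class:`EventDFAError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs or parameters.
"""


class EventDFAError(Exception):
    """Base class for all eventdfa errors."""


class ParameterError(EventDFAError, ValueError):
    """An invalid parameter value (e.g. pruning bounds with lo >= hi, mu <= 1)."""


class InvalidInputError(EventDFAError, ValueError):
    """Input data violates a precondition (wrong sign, mixed subjects, ...)."""


class InsufficientDataError(EventDFAError, ValueError):
    """Too few samples/windows to carry out the requested analysis."""


class WindowError(EventDFAError, ValueError):
    """A DFA window size is infeasible for the profile length."""


class FitError(EventDFAError, ValueError):
    """The log-log scaling fit cannot be computed (e.g. F(w) = 0 in range)."""


class DegenerateRateError(EventDFAError, ZeroDivisionError):
    """A rate is undefined (e.g. commission rate with zero friendly trials)."""


class DegenerateTestError(EventDFAError, ValueError):
    """A statistical test is degenerate (e.g. all paired differences zero)."""


class SingularFitError(EventDFAError, ValueError):
    """A regression design matrix is singular (e.g. constant predictor)."""


class CalibrationDomainError(EventDFAError, ValueError):
    """A temporal-complexity index outside the calibrated (1, 3) regime."""
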