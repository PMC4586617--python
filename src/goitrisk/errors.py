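"""Exception hierarchy for goitrisk.

Every error the library raises derives from :class:`GoitriskError`, so
callers (including the CLI) can map failures onto exit codes without
string-matching messages.
"""


class GoitriskError(Exception):
    """Base class for all goitrisk errors."""


class InvalidDistributionError(GoitriskError, ValueError):
    """Distribution parameters are non-finite or outside their domain."""


class InconsistentTargetsError(GoitriskError, ValueError):
    """Percentile targets are not strictly increasing with probability."""


class UnderdeterminedError(GoitriskError, ValueError):
    """Not enough information to identify the requested parameters."""


class SchemaError(GoitriskError, ValueError):
    """A configuration document violates the scenario schema."""


class LookupErrorGoitrisk(GoitriskError, KeyError):
    """Unknown age group, agent, basis or approach name."""


class EmptyInputError(GoitriskError, ValueError):
    """An operation received an empty sample set."""


class UndefinedShareError(GoitriskError, ZeroDivisionError):
    """Route shares requested for an agent with zero total contribution."""


class InsufficientTraceError(GoitriskError, ValueError):
    """Sample set lacks the per-factor draws needed for the decomposition."""


class CalibrationFailureError(GoitriskError, RuntimeError):
    """Calibration objective stayed above threshold after all restarts."""

    def __init__(self, message, residuals=None, objective_value=None):
        super().__init__(message)
        self.residuals = residuals or {}
        self.objective_value = objective_value


class NonConvergenceError(GoitriskError, RuntimeError):
    """Sample-size escalation hit its cap without meeting the stability rule."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
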