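"""Exception hierarchy.

Every error carries an ``exit_code`` so the command-line layer can map
failure categories to distinct process exit statuses:

===========================  ====
validation / configuration     2
non-convergence                3
protocol / message exchange    4
numerical (overflow, rank)     5
===========================  ====
"""


class ModPoisError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(ModPoisError):
    """Input data violate a structural requirement (domains, shapes, columns)."""

    exit_code = 2


class ConfigurationError(ModPoisError):
    """A model or simulation configuration is inconsistent."""

    exit_code = 2


class NonConvergenceError(ModPoisError):
    """Newton-Raphson failed to meet the convergence criterion.

    Carries the per-iteration trace so the path to failure can be inspected.
    """

    exit_code = 3

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class ProtocolError(ModPoisError):
    """A distributed-protocol rule was violated (missing/duplicate/stale message)."""

    exit_code = 4


class DeserializationError(ProtocolError):
    """A message file failed schema or payload validation."""

    exit_code = 4


class NumericalOverflowError(ModPoisError):
    """A linear predictor is large enough to overflow ``exp`` in double precision."""

    exit_code = 5


class SingularSystemError(ModPoisError):
    """The Hessian is singular or numerically rank-deficient."""

    exit_code = 5

    def __init__(self, message, suspect_columns=None):
        super().__init__(message)
        self.suspect_columns = list(suspect_columns) if suspect_columns else []
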