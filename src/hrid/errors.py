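"""Exception hierarchy for hrid.

All errors derive from :class:`HridError` so callers can catch the package's
failures with a single except clause; subclasses distinguish bad file content,
bad sampling grids, bad parameter values and optimisation failures.
"""


class HridError(Exception):
    """Base class for all hrid errors."""


class FormatError(HridError):
    """A file does not conform to the canonical CSV/sidecar layout."""


class SamplingError(HridError):
    """A time grid is not uniform at the declared sample period."""


class DataError(HridError):
    """Samples or record collections are invalid (NaN, duplicates, mismatch)."""


class StateError(HridError):
    """An operation was applied to a record in the wrong preprocessing state."""


class ParameterError(HridError):
    """Missing/extra parameters for a model structure."""


class DomainError(HridError):
    """A parameter value outside its mathematical or physiological domain."""


class ExcitationError(HridError):
    """Input signal carries no excitation (constant input)."""


class ConvergenceError(HridError):
    """No optimisation start converged."""


class ConfigurationError(HridError):
    """Inconsistent configuration (e.g. synthetic truth outside bounds)."""
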