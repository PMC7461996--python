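"""Exception hierarchy for echodraw."""


class EchodrawError(Exception):
    """Base class for all echodraw errors."""


class InvalidParameterError(EchodrawError, ValueError):
    """A network or generator parameter violates its contract."""


class ShapeError(EchodrawError, ValueError):
    """Array arguments have inconsistent shapes."""


class ConfigurationError(EchodrawError, ValueError):
    """Incompatible configuration, e.g. mismatched time steps."""


class DataError(EchodrawError, ValueError):
    """Problem with a dataset, labels or targets."""


class UndefinedMetricError(EchodrawError, ValueError):
    """A metric is undefined for the given inputs (e.g. R_S = 0)."""


class NumericalError(EchodrawError, RuntimeError):
    """Training produced non-finite values."""
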