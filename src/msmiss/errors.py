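"""Structured exceptions for configuration, estimation, and pipeline failures."""


class MsmissError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MsmissError):
    """A configuration field is invalid; the message names the field."""


class SchemaError(MsmissError):
    """A file does not conform to the documented dialect or YAML schema."""


class EstimationError(MsmissError):
    """A model fit failed (separation, non-convergence, rank deficiency)."""


class PositivityError(EstimationError):
    """A fitted probability is numerically 0 or 1 where positivity is required."""


class CalibrationError(MsmissError):
    """The missingness intercept cannot reach the requested target proportion."""


class EmptyAnalysisError(MsmissError):
    """No subjects remain after a missing-data restriction."""


class UnsupportedMethodError(MsmissError):
    """The requested method cannot handle the panel (e.g. missing exposure for MPA)."""


class OracleError(MsmissError):
    """The requested truth oracle does not apply to the given data-generating model."""


class BootstrapError(MsmissError):
    """Too many bootstrap replicates failed for the interval to be trusted."""


class ScenarioInstabilityError(MsmissError):
    """More than the tolerated share of simulation replicates failed for a method."""
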