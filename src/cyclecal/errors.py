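"""Exception hierarchy shared across the pipeline.

The command-line driver maps these onto exit codes: configuration
problems (2), malformed or insufficient data (3), numerical failures
during estimation (4).
"""


class CycleCalError(Exception):
    """Base class for all package errors."""


class ConfigError(CycleCalError, ValueError):
    """Invalid configuration: bad bounds, probabilities, paths, flags."""


class DataError(CycleCalError, ValueError):
    """Malformed or insufficient input data."""


class EstimationError(CycleCalError, RuntimeError):
    """Numerical failure while fitting: singular design, degenerate covariance."""


class PredictionError(CycleCalError, ValueError):
    """A calendar predictor produced (or would produce) an invalid day offset."""
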