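"""Exception hierarchy for the evaluation pipeline.

Every failure mode that callers are expected to handle programmatically has
its own class so that report assembly can capture errors per analysis block
without string matching.
"""


class PrsBenchError(Exception):
    """Base class for all package errors."""


class ConfigError(PrsBenchError):
    """Invalid configuration: missing columns, bad band definitions, etc."""


class ValidationError(PrsBenchError):
    """Input table violates a structural invariant (duplicate ids, ...)."""


class DegenerateScoreError(PrsBenchError):
    """A score (or trait) has zero variance in the analysis subgroup."""


class SeparationError(PrsBenchError):
    """Logistic/Cox likelihood is monotone: the outcome is perfectly
    separated by the linear predictor, so the MLE does not exist."""


class ConvergenceError(PrsBenchError):
    """An iterative fit did not converge within the iteration budget."""


class GatedError(PrsBenchError):
    """An analysis was requested on a stratum below its case-count gate."""


class EstimationError(PrsBenchError):
    """Estimation is impossible on the given data (no events, no cases,
    empty intersection of keys, target risk out of achievable range...)."""
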