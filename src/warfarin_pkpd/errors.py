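"""Exception hierarchy.

Domain errors carry the name of the failing sub-expression so callers
(notably the MAP fitter) can penalize invalid parameter proposals instead
of crashing.
"""

from __future__ import annotations


class WarfarinPKPDError(Exception):
    """Base class for all package errors."""


class ModelDomainError(WarfarinPKPDError, ValueError):
    """A model expression was evaluated outside its mathematical domain.

    Parameters
    ----------
    term
        Name of the failing sub-expression: one of ``"inr"``,
        ``"transform-offset"`` (f + a <= 0), ``"ln-argument"``,
        ``"reciprocal"`` (1/f undefined or zero), ``"singular-target"``.
    """

    def __init__(self, term: str, message: str):
        self.term = term
        super().__init__(f"[{term}] {message}")


class MetricError(WarfarinPKPDError, ValueError):
    """An anticoagulation index could not be computed from the visits given."""


class SchemaError(WarfarinPKPDError, ValueError):
    """A delimited-text table violated its schema (carries file/line context)."""


class PipelineError(WarfarinPKPDError, RuntimeError):
    """A cohort-pipeline stage failed; message is tagged with the stage name."""


class GenerationError(WarfarinPKPDError, RuntimeError):
    """Synthetic-cohort generation produced a model-invalid configuration."""
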