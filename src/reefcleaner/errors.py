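"""Exception hierarchy shared across the pipeline.

Validation problems (bad arguments, schema violations, degenerate inputs)
derive from :class:`ValidationError`; failures that can only be detected at
run time (non-estimable fits, infeasible packing) derive from
:class:`RuntimeFailure`.  The CLI maps the two branches onto exit codes
1 and 2 respectively.
"""

from __future__ import annotations


class ReefCleanerError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ReefCleanerError):
    """Invalid arguments, configuration, or input-table schema."""


class InvalidArgumentError(ValidationError):
    pass


class SchemaError(ValidationError):
    """An input table is missing columns or contains malformed rows."""


class MissingDataError(ValidationError):
    """A cross-reference (species trait, survey year) could not be resolved."""


class DegeneratePredictorError(ValidationError):
    """A predictor column has zero variance and cannot be standardized."""


class InvalidComparisonError(ValidationError):
    """Two fits are not nested / not on the same data, so no test applies."""


class NotApplicableError(ValidationError):
    """The requested diagnostic is undefined for this model family."""


class UndefinedStatisticError(ValidationError):
    """A statistic is undefined (e.g. zero-variance correlation input)."""


class RuntimeFailure(ReefCleanerError):
    """Failures surfacing during computation rather than validation."""


class PlacementError(RuntimeFailure):
    """Station packing infeasible within the retry cap."""


class NonEstimableError(RuntimeFailure):
    """A downstream quantity depends on a fit that did not converge."""
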