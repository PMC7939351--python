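"""Exception hierarchy for the isoglyco pipeline."""


class IsoglycoError(Exception):
    """Base class for all package errors."""


class DomainError(IsoglycoError, ValueError):
    """An input lies outside the mathematically valid domain."""


class InsufficientDataError(IsoglycoError, ValueError):
    """Too few observations for the requested operation."""


class MissingDataError(IsoglycoError, ValueError):
    """Required samples (e.g. a summary window) are absent."""


class EnrichmentUnderflowError(DomainError):
    """Tracer enrichment is non-positive where a Steele division is needed."""


class AlignmentError(IsoglycoError, ValueError):
    """Trajectories expected on a common time grid are misaligned."""


class DesignError(IsoglycoError, ValueError):
    """A regression design matrix is rank deficient or mis-specified."""


class SchemaError(IsoglycoError, ValueError):
    """An input table is missing mandatory columns or violates its schema."""


class SimulationError(IsoglycoError, RuntimeError):
    """The forward simulator failed to produce a valid trajectory."""


class FitError(IsoglycoError, RuntimeError):
    """A model fit or bootstrap failed beyond the tolerated rate."""
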